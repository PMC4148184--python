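"""The aberration state space and its transition geometry.

Enumerates the 21 ordered parent-specific copy-number states (total copies
capped at 5), shows how mirror pairs collapse to the 12 report categories,
and builds the normal-hub transition matrix whose stationary distribution
puts 10% of markers in aberrant states with a mean event length of 600
markers.
"""

import numpy as np

from haplomix import (
    AberrationTPMSpec,
    build_tpm,
    enumerate_states,
    stationary_distribution,
)

space = enumerate_states(5)
print(f"{len(space)} ordered states: {space.labels}")
print(f"{space.n_categories} report categories: {space.categories}")
i = space.labels.index("2-0")
print("mirror of 2-0 is", space.states[space.mirror_index[i]].label)

spec = AberrationTPMSpec(mean_event_markers=600, aberrant_fraction=0.1)
tpm = build_tpm(spec, space)
pi = stationary_distribution(spec, space)
ni = space.normal_state_index
print(f"\nnormal-state self-transition: {tpm[ni, ni]:.6f}")
print(f"aberrant exit probability:    {tpm[0, ni]:.6f}  (= 1/600)")
print(f"stationary aberrant mass:     {1 - pi[ni]:.3f}  (= design fraction)")
print(f"mean aberrant sojourn:        {1 / tpm[0, ni]:.0f} markers")
assert np.allclose(pi @ tpm, pi)
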