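"""How small a cn-LOH region can be localized at a given purity?

Plants a single cn-LOH region of increasing physical size mid-chromosome at
370K-array density (1 marker / 9 kb), decodes each sample, and reports the
smallest length for which the majority of markers in the region are called
aberrant in the majority of replicates.
"""

from haplomix import detection_ladder

result = detection_ladder(
    purity=0.05,
    lengths_mb=[0.5, 1, 2, 3, 4],
    replicates=3,
    seed=1,
    markers_per_chrom=6000,  # a 54 Mb chromosome keeps this example quick
)
print(result.table.to_string(index=False))
print(f"\nsmallest detected cn-LOH region at 5% purity: "
      f"{result.smallest_detected_mb} Mb")
print("(each n_markers column entry is the region size in markers; a "
      "replicate counts as detected when >50% of those markers get an "
      "aberrant modal category)")
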