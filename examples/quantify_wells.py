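"""Relative qPCR quantification from raw Cq values.

Builds a plasmid dilution series for two genes, fits standard curves,
back-transforms duplicate Cq readings to log2 relative quantities, and
applies housekeeping normalization.
"""

from moltmark import WellRecord, fit_standard_curve, normalize, quantify

# ten-fold dilution series: a perfect doubling assay has slope -3.32
curves = {
    gene: fit_standard_curve(
        gene, [(q, intercept - 3.3219 * q) for q in (3.0, 4.0, 5.0, 6.0)]
    )
    for gene, intercept in [("Torso-like", 36.0), ("EF1a", 33.0)]
}
for gene, c in curves.items():
    print(f"{gene}: slope {c.slope:.3f}, efficiency {c.efficiency:.2f}, R^2 {c.r_squared:.4f}")

wells = [
    WellRecord("d8_r1", "Torso-like", (24.10, 24.18), day=8.0, replicate=1),
    WellRecord("d8_r1", "EF1a", (19.02, 18.94), day=8.0, replicate=1),
    WellRecord("d8_r2", "Torso-like", (23.71, 23.77), day=8.0, replicate=2),
    WellRecord("d8_r2", "EF1a", (18.88, 18.96), day=8.0, replicate=2),
]
raw = quantify(wells, curves, housekeeping_genes=("EF1a",))
print("\nun-normalized log2 quantities:")
print(raw.values.round(3))

norm = normalize(raw)
print("\nnormalized (reference-gene geometric mean subtracted):")
print(norm.values.round(3))
# A normalized value of 0 would mean expression equal to the reference
# genes; negative values mean lower expression than the references.
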