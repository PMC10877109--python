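"""Generate a phantom biopsy cohort and inspect its ground truth.

Creates 6 phantom slides (2 HCC-like, 2 iCCA-like, 2 mixed), writes them
in the real-data interchange formats (PNG slides, GeoJSON annotations,
CSV manifests) and prints the cohort manifest.
"""

from histoclust.phantom import generate_cohort, write_cohort

cohort = generate_cohort(n_A_pure=2, n_B_pure=2, n_mixed=2, seed=7)
write_cohort(cohort, "phantom_cohort")

print(cohort.manifest.to_string(index=False))
print()
print("IHC cell counts (positives track the true contingent fraction):")
print(cohort.ihc_counts.to_string(index=False))
# true_fraction_A is the HCC-like share of tumour pixels: 1.0 for pure
# HCC-like slides, 0.0 for pure iCCA-like, in (0.2, 0.8) for mixed ones.
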