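"""Print the closed-form AGMR/HGMR expectations per relationship class.

These analytic values, computed by exact polynomial integration over
allele frequencies uniform on (0.1, 0.9), parameterize the classifier
and predict what the mismatch statistics of each relationship look like
on a 10,000-SNP fingerprint panel.
"""

from kinprint import theory
from kinprint.theory import PROFILES, ScanDesign

print("relationship  P(Z=0,1,2)        E[AGMR]  E[HGMR]  SD[HGMR]@10k")
for rel in ("ID", "PO", "FS", "D2", "D3", "UN"):
    p = PROFILES[rel]
    print(f"{rel:>12}  ({p.p0:.2f},{p.p1:.2f},{p.p2:.2f})  "
          f"{theory.expected_agmr(p):7.4f}  {theory.expected_hgmr(p):7.4f}  "
          f"{theory.sd_hgmr(p, S=10_000):8.4f}")

print("\nearly-termination screen (m=64, k=8) false-negative rate vs "
      "pair mismatch rate:")
for eps in (0.01, 0.0238, 0.0548, 0.0749):
    fn = theory.quadratic_fn_rate(ScanDesign(m=64, k=8, epsilon=eps))
    print(f"  eps={eps:.4f}: FN={fn * 100:.3f}%")

print("\nkinship coefficients:",
      {r: theory.kinship(PROFILES[r]) for r in ("ID", "PO", "FS", "D2", "D3", "UN")})
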