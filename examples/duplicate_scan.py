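"""Find planted duplicate samples with all three scanners.

Simulates a small study with known duplicates, runs the exhaustive,
early-termination and sort-based scanners, and shows they agree.  The
AGMR of each detected pair sits near the simulated genotyping error
rate, far below the 20% identical cutoff.
"""

from kinprint import SimConfig, simulate, naive_scan, quadratic_scan, subquadratic_scan
from kinprint.simulate import plant_report

res = simulate(
    SimConfig(S=5_000, n_families=0, n_unrelated=150, n_planted_duplicates=6,
              error_rate=0.01, missing_rate=0.01, seed=42)
)
fps = res.fingerprints()
print(f"{len(fps)} samples over {fps.n_snps} panel SNPs; "
      f"{len(res.truth.duplicates)} planted duplicate pairs\n")

for scan, name in ((naive_scan, "naive"), (quadratic_scan, "quadratic")):
    pairs = scan(fps)
    rep = plant_report(res.truth, detected_duplicates={p.key() for p in pairs})
    print(f"{name:>12}: {len(pairs)} pairs, "
          f"sensitivity={rep['duplicates']['sensitivity']:.2f}, "
          f"FDR={rep['duplicates']['fdr']:.2f}")

pairs = subquadratic_scan(fps, m=20, c=10, seed=1)
rep = plant_report(res.truth, detected_duplicates={p.key() for p in pairs})
print(f"{'subquadratic':>12}: {len(pairs)} pairs, "
      f"sensitivity={rep['duplicates']['sensitivity']:.2f}, "
      f"FDR={rep['duplicates']['fdr']:.2f}\n")

for p in sorted(pairs, key=lambda p: p.id_a):
    print(f"  {p.id_a} ~ {p.id_b}: AGMR={p.stats.agmr:.4f} "
          f"({p.stats.n_compared} SNPs compared)")
print("\nAGMR near the 1% error rate marks a true duplicate; unrelated "
      "pairs sit near 54%.")
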