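"""Screen the kinetic-model catalog on a simulated accelerated study.

Generates a 21-point, 3-arm (5/25/40 degC) study of acidic-variant growth
in a mAb, checks the good-modeling-practice entry rules, then fits the
five catalog models and ranks them by combined AICc/BIC weight.
"""

import stabkin as sk
from stabkin.synthetic import generate_dataset, preset

cfg = preset("mab-acidic-variants")
ds, truth = generate_dataset(cfg, seed=42)

report = sk.validate_design(ds, cfg.transform)
print(f"design check: {report.status}")
for line in report.reasons():
    print("  " + line)

ranking = sk.screen_models(sk.default_catalog(), sk.to_extent(ds, cfg.transform),
                           design_report=report)
print(f"\n{'model':<16}{'K':>3}{'RSS':>12}{'AICc':>10}{'wComb':>8}")
for r in ranking.results:
    print(f"{r.spec.name:<16}{r.k_free:>3}{r.rss:>12.3e}{r.aicc:>10.1f}"
          f"{ranking.wcombined[r.spec.name]:>8.3f}")

best = ranking.best
print(f"\ntruth: {truth.spec.name} with Ea = {truth.params.Ea1/1000:.0f} kJ/mol")
print(f"best:  {best.spec.name} with Ea = {best.params.Ea1/1000:.1f} kJ/mol, "
      f"n = {best.params.n1:.2f}")
# The top-ranked model should match the generating nth-order structure and
# recover the activation energy within a few percent; the weights say how
# decisively the information criteria separate the candidates.
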