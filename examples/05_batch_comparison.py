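"""Batch-to-batch comparability against a reference kinetic fingerprint.

Fits batch A, builds its 99% prediction band, and asks whether batch B's
observations fall inside it — first for a true replicate batch, then for
a batch degrading twice as fast.
"""

import math

import stabkin as sk
from stabkin.kinetics import ModelCatalog, first_order_spec
from stabkin.synthetic import generate_dataset, preset

cfg = preset("live-attenuated-titer")
ds_a, _ = generate_dataset(cfg, seed=3)
ranking = sk.screen_models(ModelCatalog([first_order_spec()]),
                           sk.to_extent(ds_a, cfg.transform))
ensemble, _ = sk.residual_bootstrap(ranking, B=400, seed=8)

replicate, _ = generate_dataset(cfg, seed=99)
fast_cfg = cfg.with_(params=cfg.params.replace(lnA1=cfg.params.lnA1 + math.log(2.0)))
doubled, _ = generate_dataset(fast_cfg, seed=100)

for label, ds_b in [("replicate batch", replicate), ("2x-rate batch", doubled)]:
    cmp = sk.compare_batches(ranking.best, ensemble, ds_b, cfg.transform)
    verdict = "comparable" if cmp.comparable else "NOT comparable"
    print(f"{label:>16}: {verdict}; inclusion {cmp.inclusion_fraction:.2f}, "
          f"rate ratio at 25 degC {cmp.rate_ratio_at_ref:.2f}, "
          f"dEa {cmp.delta_Ea1/1000:+.1f} kJ/mol")
# Inclusion is the fraction of batch-B points inside batch A's 99% band;
# a genuine replicate sits near 1.0, the doubled-rate batch falls out.
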