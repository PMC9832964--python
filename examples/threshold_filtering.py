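"""How the display threshold thins a globe.

A correlation globe is usually read at several absolute-value cutoffs: low
thresholds show the full correlation structure, higher ones isolate the
strong associations. The cutoff is strict (|coef| > t), so a coefficient
sitting exactly on the threshold is not drawn.
"""

import corrglobe as cg
from corrglobe.errors import EmptyGlobe

table = cg.generate(cg.FixtureSpec(seed=12, coef_distribution="uniform"))
print(f"{len(table)} records; threshold sweep:")

for t in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
    try:
        model = cg.build_globe(table, threshold=t)
        n_neg = sum(1 for rb in model.ribbons if rb.coef < 0)
        print(f"  |coef| > {t:.1f}: {len(model.ribbons):3d} ribbons "
              f"({n_neg} negative) across {len(model.domains)} domains")
    except EmptyGlobe as exc:
        print(f"  |coef| > {t:.1f}: empty globe — {exc}")

print("ribbon counts are non-increasing in the threshold; domains whose "
      "ribbons all vanish are pruned from the rim")
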