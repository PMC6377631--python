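"""Gamma two-pathway interference fits for both sexes.

Fits the (nu, p) renewal mixture to chromatid-level CO sets from the
female/male conditions: stronger interference should appear as higher nu
and a lower non-interfering proportion p in the female set.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from gametoco.bf_sim import simulate_bivalents, to_chromatid
from gametoco.interference_stats import fit_gamma_model
from gametoco.presets import ZS_FEMALE, ZS_MALE

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260920
OUT = ROOT / "results" / "gamma"
OUT.mkdir(parents=True, exist_ok=True)

results = {}
for name, params in (("female", ZS_FEMALE), ("male", ZS_MALE)):
    bset = simulate_bivalents(params, 4000, SEED + 21)
    chrom = to_chromatid(bset, SEED + 22)
    fit = fit_gamma_model(chrom, n_sim=5000, seed=SEED + 23)
    results[name] = dict(nu=fit.nu, p=fit.p, loglik=fit.loglik)
    print(f"{name}: nu {fit.nu:.1f}, p {fit.p:.2f}")
assert results["female"]["nu"] >= results["male"]["nu"], "nu ordering"
assert results["female"]["p"] <= results["male"]["p"], "p ordering"
print("female meiosis: stronger interference (higher nu), "
      "smaller non-interfering fraction (lower p)")
with open(OUT / "gamma_fits.json", "w") as fh:
    json.dump(results, fh, indent=2)
print(f"wrote {OUT}")
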