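#!/usr/bin/env python
"""Region-specific exposure effects: the spatially varying coefficient model.

Simulates a two-region world where fine-particulate exposure raises the
gender gap in one region and lowers it in the other (the kind of
geographic sign flip the region-specific model exists to detect), fits
the M2s variant, and checks that both regional coefficients are recovered
with the right sign while the shared confounders stay global.
"""

import argparse
from pathlib import Path

from stgap import Hyperparameters, SimulationConfig, simulate_panel
from stgap.io import stamp_lines, write_summaries
from stgap.model import ModelSpec, build_model, fit_mcmc
from stgap.posterior import posterior_summary

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/regions"))
args = parser.parse_args()

REGION_TRUTH = {"Africa": (0.2, 0.251), "Americas": (-0.3, 0.251)}

config = SimulationConfig(
    n_countries=30,
    years=(2004, 2018),
    region_count=2,
    region_betas=REGION_TRUTH,
    true_hyper=Hyperparameters(
        tau_e=150.0, tau_s=5.0, phi=0.5, tau_theta=2e4, tau_delta=180.0
    ),
    seed=args.seed,
)
sim = simulate_panel(config)
state = build_model(sim.panel, sim.graph, ModelSpec(variant="M2s"))
fit = fit_mcmc(state, n_iter=1500, n_warmup=600, n_chains=2, seed=args.seed + 1)

summary = posterior_summary(fit)
args.out.mkdir(parents=True, exist_ok=True)
write_summaries(summary, args.out / "summaries_m2s.csv",
                header_lines=stamp_lines(seed=args.seed))

print("regional pwPM2.5 coefficients (posterior mean [95% CI], truth):")
both_signs_ok = True
for region, (b_pm, _) in REGION_TRUTH.items():
    row = summary[summary["quantity"] == f"beta[pwpm25|{region}]"].iloc[0]
    ok = (row["mean"] > 0) == (b_pm > 0)
    both_signs_ok &= ok
    print(f"  {region:10s} {row['mean']:+.3f} ({row['q2.5']:+.3f}, "
          f"{row['q97.5']:+.3f})   truth {b_pm:+.3f}   sign "
          f"{'recovered' if ok else 'MISSED'}")
print("both regional signs recovered" if both_signs_ok
      else "sign recovery failed for at least one region")
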