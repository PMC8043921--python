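#!/usr/bin/env python
"""Fit the 12 logistic prediction models on the simulated cohort.

M1 = clinical (histology + clinical T-stage); M2 = L1-selected radiomic
features; M3 = union; M4-M12 add HER2, CD44 or both to each reference
model.  Writes coefficients and AIC to results/models.json and an AIC table
to results/model_aic.csv.
"""

import json
from pathlib import Path

import pandas as pd

from petradiomics.models import build_model_suite, lasso_select
from petradiomics.pipeline import RunConfig, stage_seed

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cfg = RunConfig(seed=1)
    data = pd.read_csv(ROOT / "scratch" / "cohort.csv")
    selected = json.loads((RESULTS / "clusters.json").read_text())["selected"]
    if len(selected) >= 2:
        sel = lasso_select(data, selected, seed=stage_seed(cfg.seed, "lasso"))
        radiomic = sel["selected"] or selected[:1]
        print(f"L1 selection at lambda={sel['lambda']:.4f}: {radiomic}")
    else:
        radiomic = selected
        print(f"<2 screened representatives; using {radiomic} directly")

    suite = build_model_suite(data, radiomic_covariates=radiomic)
    payload = {
        name: {
            "covariates": list(m.spec.covariates),
            "coefficients": m.params.to_dict(),
            "bse": m.bse.to_dict(),
            "llf": m.llf,
            "aic": m.aic,
            "n": m.n,
            "flags": m.flags,
        }
        for name, m in suite.items()
    }
    (RESULTS / "models.json").write_text(json.dumps(payload, indent=2))
    table = pd.DataFrame(
        {"covariates": [", ".join(m.spec.covariates) for m in suite.values()],
         "n": [m.n for m in suite.values()],
         "AIC": [round(m.aic, 1) for m in suite.values()]},
        index=list(suite),
    )
    table.to_csv(RESULTS / "model_aic.csv", index_label="model")
    print(table.to_string())
    best = table["AIC"].idxmin()
    print(f"lowest AIC: {best} ({table.loc[best, 'AIC']})")


if __name__ == "__main__":
    main()
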