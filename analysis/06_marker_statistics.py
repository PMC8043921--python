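#!/usr/bin/env python
"""Marker worked examples and cluster-covariate independence checks.

Recomputes, from the bundled printed-count fixtures: the HER2 and CD44
diagnostic metrics with exact binomial CIs, the marker x T-stage Fisher
tests, the univariable LRT p-values of all six markers, and — on the
simulated cohort — the patient-cluster vs covariate association tests.
Writes results/marker_statistics.json.
"""

import json
from pathlib import Path

import pandas as pd

from petradiomics.markers import (
    ContingencyTable2x2,
    cluster_covariate_association,
    diagnostic_metrics,
    fisher_exact,
)
from petradiomics.models import encode_clinical, univariable_screen
from petradiomics.reduction import cluster_patients
from petradiomics.synthcohort import (
    fixture_clinical_group1,
    fixture_clinical_group2,
    published_fixtures,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    out = {}
    fx = published_fixtures()

    her2 = ContingencyTable2x2(a=19, b=57, c=1, d=17)  # HER2- as response test
    dm = diagnostic_metrics(her2)
    out["her2_diagnostics"] = {
        "sensitivity": dm.sensitivity.value, "sensitivity_ci": dm.sensitivity.ci,
        "npv": dm.npv.value, "npv_ci": dm.npv.ci,
    }
    print(f"HER2-negativity for response: sensitivity {dm.sensitivity.value:.0%}, "
          f"NPV {dm.npv.value:.0%}")

    cd44 = fx["cd44_response_g2"]
    dm = diagnostic_metrics(cd44)
    dual = diagnostic_metrics(ContingencyTable2x2(a=15, b=1, c=19, d=8))
    out["cd44_diagnostics"] = {
        "sensitivity": dm.sensitivity.value, "ppv_dual": dual.ppv.value,
    }
    print(f"CD44-positivity for response: sensitivity {dm.sensitivity.value:.0%}; "
          f"CD44-negativity for non-response: PPV {dual.ppv.value:.0%}")

    out["fisher"] = {
        "her2_tstage": fisher_exact(fx["her2_tstage_g1"]),
        "cd44_tstage": fisher_exact(fx["cd44_tstage_g2"]),
    }
    print(f"Fisher exact: HER2 x T-stage p={out['fisher']['her2_tstage']:.3f}, "
          f"CD44 x T-stage p={out['fisher']['cd44_tstage']:.3f}")

    g1 = encode_clinical(fixture_clinical_group1())
    g2 = encode_clinical(fixture_clinical_group2())
    lrt = {"her2": univariable_screen(g1.dropna(subset=["her2"]), ["her2"]).loc["her2", "p"]}
    for marker in ("cd44", "hif1a_nucleus", "hif1a_cytosol", "ptch1", "shh"):
        sub = g2.dropna(subset=[marker])
        lrt[marker] = univariable_screen(sub, [marker]).loc[marker, "p"]
    out["univariable_lrt_p"] = lrt
    print("univariable LRT p (markers):",
          {k: round(v, 3) for k, v in lrt.items()})
    print("preselected at p<0.2:", [k for k, v in lrt.items() if v < 0.2])

    data = pd.read_csv(ROOT / "scratch" / "cohort.csv")
    feats = data[[c for c in data.columns if c.startswith("feat_")]]
    _, passign = cluster_patients(feats)
    assoc = {}
    for cov in ("histology_squamous", "cT_T3-4a", "cN_N2-3", "her2", "cd44"):
        res = cluster_covariate_association(passign.assignment.to_numpy(), data[cov])
        assoc[cov] = {"p": res.p_value, "method": res.method}
    out["cluster_covariate_associations"] = assoc
    print(f"{passign.n_clusters} patient clusters; covariate association p-values:",
          {k: round(v["p"], 3) for k, v in assoc.items()})

    (RESULTS / "marker_statistics.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {RESULTS/'marker_statistics.json'}")


if __name__ == "__main__":
    main()
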