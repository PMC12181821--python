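"""Pooled probable prevalence, comorbidity and severity associations.

Applies the three ICD-11 diagnostic algorithms to every completed
dataset, pools counts and proportions, pools Fisher-z severity
correlations across imputations, and reports McDonald's omega for the
TGI-SR+ items. Writes prevalence.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from griefnet.data import TGI_ITEMS
from griefnet.imputation import ImputationStack, pool_correlation
from griefnet.pipeline import read_cohort
from griefnet.scoring import diagnose_all, mcdonald_omega, prevalence_and_comorbidity


def pooled_severity_correlations(stack, meta) -> dict:
    pairs = [("severity_pgd", "severity_ptsd"), ("severity_pgd", "severity_dso"),
             ("severity_pgd", "severity_cptsd"), ("severity_ptsd", "severity_dso")]
    rs = {p: [] for p in pairs}
    for d in stack.datasets:
        sev = diagnose_all(d.values, meta)
        for a, b in pairs:
            rs[(a, b)].append(float(np.corrcoef(sev[a], sev[b])[0, 1]))
    n = stack.datasets[0].n
    return {f"{a[9:]}_vs_{b[9:]}": round(pool_correlation(v, n).point, 3)
            for (a, b), v in rs.items()}


def main(seed: int = 0, out: str = "results") -> None:
    out_dir = Path(out)
    items, meta = read_cohort(out_dir / "cohort.csv")
    stack = ImputationStack.from_long(pd.read_csv(out_dir / "imputations_long.csv"))

    summary = prevalence_and_comorbidity(stack, meta)
    summary["pooled_severity_correlations"] = pooled_severity_correlations(stack, meta)
    omegas = [mcdonald_omega(d.values[list(TGI_ITEMS)]).omega_total for d in stack.datasets]
    summary["omega_tgi_pooled"] = round(float(np.mean(omegas)), 3)

    (out_dir / "prevalence.json").write_text(json.dumps(summary, indent=2))
    pp = summary["proportions_pct"]
    print(f"pooled probable prevalence (N={summary['n']}, m={summary['m']}): "
          f"PGD {pp['pgd']:.2f}%, PTSD {pp['ptsd_icd11']:.2f}%, cPTSD {pp['cptsd']:.2f}%")
    cond = summary["conditional_on_pgd_pct"]
    print(f"among probable PGD cases: {cond['ptsd_icd11']:.2f}% comorbid PTSD, "
          f"{cond['cptsd']:.2f}% comorbid cPTSD")
    print(f"TGI-SR+ omega (pooled): {summary['omega_tgi_pooled']}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    a = ap.parse_args()
    main(a.seed, a.out)
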