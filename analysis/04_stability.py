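"""Bootstrap stability of the baseline network.

Edge-weight 95% confidence intervals (non-parametric bootstrap) and
correlation-stability coefficients of the centrality indices
(case-dropping bootstrap).  Replicate counts are configurable; the
defaults keep a desk run to well under a minute.
"""

import argparse
from pathlib import Path

from symptomnet.scale import complete_cases, load_cohort
from symptomnet.stability import bootstrap_edges, case_drop_bootstrap, cs_coefficient

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results/stability"))
parser.add_argument("--boots", type=int, default=1000, help="edge-bootstrap replicates")
parser.add_argument("--cs-boots", type=int, default=250, help="case-drop replicates per proportion")
args = parser.parse_args()

matrix = complete_cases(load_cohort(args.cohort), "assessment")
args.out_dir.mkdir(parents=True, exist_ok=True)

edges = bootstrap_edges(matrix, B=args.boots, seed=args.seed)
edges.table.to_csv(args.out_dir / "edge_bootstrap.csv", index=False)
width = (edges.table["hi95"] - edges.table["lo95"]).mean()
print(f"edge bootstrap: B={args.boots}, mean 95% CI width {width:.3f}")

res = case_drop_bootstrap(matrix, B_per=args.cs_boots, seed=args.seed)
res.quantiles.to_csv(args.out_dir / "cs_quantiles.csv", index=False)
cs = cs_coefficient(res)
cs.to_csv(args.out_dir / "cs_coefficients.csv", index=False)
print(cs.to_string(index=False))
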