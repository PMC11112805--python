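"""Node centrality (strength, closeness, betweenness) at every wave.

Writes long-format centrality tables and prints the top nodes per index
at baseline; the planted hubs (mental stamina, experience of demands)
should lead strength, and sleep/irritation should trail.
"""

import argparse
from pathlib import Path

from symptomnet.centrality import INDICES, centrality_long, centrality_table
from symptomnet.network import estimate_network
from symptomnet.scale import complete_cases, load_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results/centrality"))
args = parser.parse_args()

cohort = load_cohort(args.cohort)
args.out_dir.mkdir(parents=True, exist_ok=True)

tables = {}
for tp in cohort.present_timepoints():
    table = centrality_table(estimate_network(complete_cases(cohort, tp)))
    tables[tp] = table
    centrality_long(table).to_csv(args.out_dir / f"centrality_{tp}.csv", index=False)

baseline = cohort.present_timepoints()[0]
t = tables[baseline]
for index in INDICES:
    ranked = t.sort_values(index, ascending=False)["node"].tolist()
    print(f"{index:>12}: top {ranked[:2]}  bottom {ranked[-2:]}")
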