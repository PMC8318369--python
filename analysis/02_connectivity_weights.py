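"""Build the population-weighted, alter-state-restricted connectedness weights.

Reproduces the weight construction used for spillover exposures: gravity SCI
scores are rescaled by alter population, same-state alters are removed, and
each ego row is renormalized to a probability vector.  Writes a per-ego
summary (top alter, out-of-state weight concentration) to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from policyspill import SimConfig, simulate_all
from policyspill.connectivity import population_weight_sci, restrict_to_alter_states
from policyspill.io import write_table

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    world = simulate_all(SimConfig(seed=SEED), dyads=False)
    geo = world["geography"].set_index("county")
    matrix = restrict_to_alter_states(
        population_weight_sci(world["sci"], geo["population"]), geo["state"]
    )

    top_alter = matrix.alters[np.argmax(matrix.weights, axis=1)]
    summary = pd.DataFrame(
        {
            "ego": matrix.egos,
            "top_alter": top_alter,
            "top_weight": matrix.weights.max(axis=1),
            "effective_alters": 1.0 / (matrix.weights ** 2).sum(axis=1),
        }
    )
    write_table(summary, ROOT / "results" / "02_weights_summary.csv")

    print(f"egos: {len(matrix.egos)}, flagged (no out-of-state mass): "
          f"{len(matrix.flagged_egos)}")
    print(f"median top-alter weight: {summary['top_weight'].median():.3f}")
    print(f"median effective number of alters: {summary['effective_alters'].median():.1f}")
    print("row sums (should all be 1):",
          np.round(matrix.row_sums().describe()[['min', 'max']].to_numpy(), 12))


if __name__ == "__main__":
    main()
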