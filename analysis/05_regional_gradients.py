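"""Superior-vs-inferior regional comparison of counter-gradient genes.

Simulates the classic dorsoventral opsin counter-gradient (an M-opsin-like
gene enriched superiorly, an S-opsin-like gene enriched inferiorly, 4-fold,
n=4 per region) and tests each gene with an unpaired two-tailed Student's t
on log2(x+1) expression, reporting fold changes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isoswitch.io_utils import write_tsv
from isoswitch.profiles import regional_comparison

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7
FOLD = 4.0


def main() -> None:
    rng = np.random.default_rng(SEED)
    n = 4
    high, low = 200.0, 200.0 / FOLD
    cols, regions = {}, {}
    for i in range(n):
        cols[f"sup{i+1}"] = [high * rng.lognormal(0, 0.1), low * rng.lognormal(0, 0.1)]
        regions[f"sup{i+1}"] = "superior"
    for i in range(n):
        cols[f"inf{i+1}"] = [low * rng.lognormal(0, 0.1), high * rng.lognormal(0, 0.1)]
        regions[f"inf{i+1}"] = "inferior"
    matrix = pd.DataFrame(cols, index=["M_opsin_like", "S_opsin_like"])

    res = regional_comparison(matrix, regions, list(matrix.index))
    write_tsv(RESULTS / "regional_comparison.tsv", res.reset_index(), index=False,
              seed=SEED)
    print(res.round(4).to_string())
    print("opposite t signs confirm the counter-gradient; "
          f"simulated fold was {FOLD}")


if __name__ == "__main__":
    main()
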