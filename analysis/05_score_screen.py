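"""Score the simulated screen: z-scores vs controls, 2-SD hit calling,
normoxia counter-screen exclusion, and a ranked-hit figure.

Run from the repository root:  python analysis/05_score_screen.py
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from sgquant import PipelineConfig
from sgquant.pipeline import run_screen

SCREEN = Path("results/screen")


def main() -> None:
    hyp = pd.read_csv(SCREEN / "plate_hypoxia.csv")
    norm = pd.read_csv(SCREEN / "plate_normoxia.csv")
    config = PipelineConfig(outdir=str(SCREEN))
    out = run_screen(config, hyp, norm)
    print((SCREEN / "screen_report.txt").read_text().rstrip())

    top = out["scored"].ranked_drugs().head(100)
    fig, ax = plt.subplots(figsize=(10, 4))
    colors = ["crimson" if w in set(out["excluded"]["well_id"]) else "steelblue"
              for w in top["well_id"]]
    ax.bar(range(len(top)), top["z"], color=colors, width=0.9)
    ax.axhline(2.0, color="gray", ls="--", lw=1, label="2 SD hit threshold")
    ax.set_xlabel("drug rank")
    ax.set_ylabel("z-score (granules/cell vs controls)")
    ax.set_title("Top 100 drugs by stress-granule retention z-score "
                 "(red = excluded by normoxia counter-screen)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(SCREEN / "top100_zscores.png", dpi=120)
    print(f"figure -> {SCREEN / 'top100_zscores.png'}")


if __name__ == "__main__":
    main()
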