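#!/usr/bin/env python
"""Compare qNMR against UV colorimetry on six production batches.

Recomputes the paired t statistics from the packaged batch table and
writes results/method_comparison.json.
"""

import json
from pathlib import Path

from dtsq import datasets
from dtsq.validation import paired_comparison

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = datasets.load_method_comparison()
    res = paired_comparison(table["uv"], table["qnmr"])
    print(f"column means: UV {table['uv'].mean():.2f}, "
          f"qNMR {table['qnmr'].mean():.2f} mmol/L")
    print(f"mean relative deviation {res.mean_relative_deviation:.2f}%")
    print(f"paired t: mean difference {res.mean_difference:.3f} mmol/L, "
          f"95% CI ({res.conf_int[0]:.3f}, {res.conf_int[1]:.3f}), "
          f"t({res.df}) = {res.t_statistic:.3f}, p = {res.p_value:.3f}")
    verdict = "no significant difference" if res.p_value > 0.05 else "methods differ"
    print(f"-> {verdict} between the two methods at the 5% level")

    OUT.mkdir(exist_ok=True)
    with open(OUT / "method_comparison.json", "w") as fh:
        json.dump({
            "mean_uv": table["uv"].mean(), "mean_qnmr": table["qnmr"].mean(),
            "mean_relative_deviation_pct": res.mean_relative_deviation,
            "mean_difference": res.mean_difference,
            "conf_int_95": list(res.conf_int),
            "t_statistic": res.t_statistic, "df": res.df,
            "p_value": res.p_value,
        }, fh, indent=2)


if __name__ == "__main__":
    main()
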