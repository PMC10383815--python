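#!/usr/bin/env python
"""Screen seven acquisition parameters with the packaged Plackett-Burman study.

Fits first-order models of accuracy, SNR and resolution on the 15-run
two-level design and flags the critical parameters whose 95% coefficient
intervals exclude zero.  Writes the coefficient-plot tables and a JSON
model report under results/.
"""

from pathlib import Path

from dtsq import datasets
from dtsq.doe import validate_two_level
from dtsq.modeling import coefficient_plot_table, fit_screening, write_model_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = datasets.load_pbd()
    validate_two_level(design)
    print("screening design: 12 orthogonal two-level runs + 3 centers")

    OUT.mkdir(exist_ok=True)
    models = []
    for response in design.responses.columns:
        fitted = fit_screening(design, response)
        models.append(fitted)
        coefficient_plot_table(fitted).to_csv(
            OUT / f"screening_coefficients_{response}.csv", float_format="%.6g")
        print(f"{response:10s} r2 {fitted.r2:.3f}  significant: "
              f"{sorted(fitted.significant_factors)}")
    write_model_report(OUT / "screening_models.json", models)
    print("NS drives SNR and D1/TD drive accuracy -> NS, TD and D1 are the "
          "critical parameters optimized in 03.")


if __name__ == "__main__":
    main()
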