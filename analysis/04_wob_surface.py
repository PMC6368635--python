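#!/usr/bin/env python
"""The closed-form WOB surface and the compensating pressure support.

Evaluates WOB(PS, f_B) = -(1.24 f_B + 0.89)(PS - 14)/13 over the studied
grid and the compensating PS(f_B) = 14 - 399.1/(1.24 f_B + 0.89), i.e. the
support at which assisted WOB equals the 30.7 mJ/breath unassisted anchor.

Writes results/wob_surface.tsv.
"""

import pandas as pd

from sbtsim.experiments import WOBSurface


def main() -> None:
    s = WOBSurface()
    rows = []
    for rate in (24.0, 28.0, 32.0, 36.0):
        for ps in range(0, 15):
            rows.append({"rate": rate, "pressure_support": ps,
                         "wob_mj": round(s.wob(float(ps), rate), 2)})
    pd.DataFrame(rows).to_csv("results/wob_surface.tsv", sep="\t", index=False)

    print("compensating pressure support vs respiratory rate:")
    for rate in (20.0, 24.0, 28.0, 32.0, 36.0, 40.0):
        raw = s.compensating_ps(rate)
        print(f"  {rate:4.0f}/min: PS = {raw:5.2f} cmH2O "
              f"(whole-cmH2O setting {s.compensating_ps_integer(rate)})")
    print(f"\nAt 24/min the tube load is compensated by ~1 cmH2O of support; "
          f"at 36/min it takes {s.compensating_ps(36.0):.2f} (set 6) cmH2O: "
          "the support needed to offset a neonatal tube depends strongly on "
          "respiratory rate.")


if __name__ == "__main__":
    main()
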