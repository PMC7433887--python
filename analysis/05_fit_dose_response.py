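"""Fit 4PL dose-response curves to the phenotypic distances.

Produces the EC50 summary table (with fit / No-fit status) from the
per-well distances of the demo screen.
"""

import pandas as pd
from config import CONTROL, RESULTS

from organoidscreen.doseresponse import curve_from_distances, fit_4pl


def main():
    dist = pd.read_csv(RESULTS / "demo_distances.csv")
    rows = []
    for comp, sub in dist.groupby("trained_on"):
        frame = sub.rename(columns={"well_id": "well"})
        curve = curve_from_distances(frame, comp, CONTROL)
        rows.append(fit_4pl(curve).as_dict())
    fits = pd.DataFrame(rows)
    fits.to_csv(RESULTS / "demo_fits.csv", index=False)
    for r in fits.itertuples():
        label = (f"EC50 {r.ec50_nM:.1f} nM (hill {r.hill:.2f}, "
                 f"r2 {r.r_squared:.2f})" if r.status == "fit"
                 else f"No fit ({r.reason})")
        print(f"{r.compound}: {label}")


if __name__ == "__main__":
    main()
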