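"""Simulate the demo screen: two-channel z-stacks for every well.

Writes <well>_dapi.tif / <well>_actin.tif stacks plus layout.csv and
ground_truth.csv to the plate directory.
"""

from config import ACQ, COMPOUNDS, DESIGN, PHENO, PLATE_DIR, SEED, TOP_DOSES

from organoidscreen import generate_screen


def main():
    layout, gt, out = generate_screen(DESIGN, COMPOUNDS, PHENO, ACQ,
                                      seed=SEED, out_dir=PLATE_DIR,
                                      top_doses=TOP_DOSES)
    n_treated = (layout["role"] == "treated").sum()
    print(f"wrote {len(layout)} wells ({n_treated} treated, "
          f"{len(layout) - n_treated} control) to {out}")
    print(f"{len(gt)} ground-truth organoids; "
          f"theta range {gt['theta'].min():.2f}-{gt['theta'].max():.2f}")


if __name__ == "__main__":
    main()
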