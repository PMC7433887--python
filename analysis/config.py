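"""Shared demo-screen configuration for the numbered analysis scripts.

A deliberately small screen (2 compounds, 3 replicates, 128x128 frames)
so the whole chain runs in about a minute on one CPU. Image stacks and
label masks go under scratch/ (bulky, regenerable); tables and fitted
models go under results/.
"""

from pathlib import Path

from organoidscreen import (AcquisitionParams, CompoundModel,
                            PhenotypeParams, PlateDesign)

ROOT = Path(__file__).resolve().parents[1]
PLATE_DIR = ROOT / "scratch" / "demo_plate"
MASK_DIR = ROOT / "scratch" / "demo_masks"
RESULTS = ROOT / "results"

SEED = 20

ACQ = AcquisitionParams(frame_shape=(128, 128))
PHENO = PhenotypeParams(n_organoids=4)
DESIGN = PlateDesign(n_replicates=3, n_control_wells=6)
COMPOUNDS = [CompoundModel("C1", ec50=2.0),
             CompoundModel("C2", ec50=36.0)]
TOP_DOSES = {"C1": 100.0, "C2": 250.0}
CONTROL = "DMSO"
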