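"""End-to-end screen analysis: stacks → masks → features → distances → EC50.

Chains the per-module operations over a whole simulated (or loaded) plate.
Accepts either an in-memory ``{well: ImageStack}`` mapping or a plate
directory written by ``simulate.generate_screen``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .core import AcquisitionParams, ImageStack
from .morphometry import (WellProfile, aggregate_well,
                          extract_organoid_features, profiles_to_frame)
from .phenoscore import FeatureSelection, score_wells, train_feature_space
from .doseresponse import fit_screen
from .segmentation import SegmentationParams, segment_well
from .simulate import load_well_stack


def profile_well(stack: ImageStack, layout_row: dict,
                 params: SegmentationParams = SegmentationParams(),
                 ) -> WellProfile:
    """Segment one well and aggregate its morphometric profile."""
    proj, masks = segment_well(stack, params)
    records = extract_organoid_features(masks, proj)
    return aggregate_well(records, layout_row, well_id=stack.well_id)


def profile_plate(layout: pd.DataFrame,
                  stacks: Optional[Dict[str, ImageStack]] = None,
                  plate_dir: Optional[str | Path] = None,
                  acq: Optional[AcquisitionParams] = None,
                  params: SegmentationParams = SegmentationParams(),
                  ) -> List[WellProfile]:
    """Per-well profiles for every layout row, from memory or from disk."""
    if stacks is None and plate_dir is None:
        raise ValueError("provide stacks or plate_dir")
    profiles = []
    for row in layout.to_dict("records"):
        well = row["well"]
        stack = (stacks[well] if stacks is not None
                 else load_well_stack(plate_dir, well,
                                      acq or AcquisitionParams()))
        profiles.append(profile_well(stack, row, params))
    return profiles


def analyze_screen(layout: pd.DataFrame,
                   stacks: Optional[Dict[str, ImageStack]] = None,
                   plate_dir: Optional[str | Path] = None,
                   acq: Optional[AcquisitionParams] = None,
                   control_label: str = "DMSO",
                   k: int = 10,
                   params: SegmentationParams = SegmentationParams(),
                   ) -> dict:
    """Full analysis of one screen.

    Returns a dict with the per-well profile table, one FeatureSelection
    and per-well distance table per compound, the per-condition summary,
    and the 4PL fit summary table.
    """
    profiles = profile_plate(layout, stacks, plate_dir, acq, params)
    compounds = sorted(c for c in layout["compound"].unique()
                       if c != control_label)
    selections: Dict[str, FeatureSelection] = {}
    distance_frames = []
    fit_rows = []
    for comp in compounds:
        sub = [p for p in profiles
               if p.metadata.get("compound") in (comp, control_label)]
        sel = train_feature_space(sub, control_label=control_label,
                                  compound=comp, k=k)
        selections[comp] = sel
        comp_dist = score_wells(sub, sel)
        distance_frames.append(comp_dist.assign(trained_on=comp))
        comp_fits = fit_screen(comp_dist.rename(columns={"well_id": "well"}),
                               control_label)
        fit_rows.append(comp_fits)
    distances = (pd.concat(distance_frames, ignore_index=True)
                 if distance_frames else pd.DataFrame())
    fits = (pd.concat(fit_rows, ignore_index=True)
            if fit_rows else pd.DataFrame())
    return {
        "profiles": profiles,
        "profile_table": profiles_to_frame(profiles),
        "selections": selections,
        "distances": distances,
        "fits": fits,
    }
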