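"""Synthetic two-channel organoid z-stack and screen generator.

Emulates a high-content confocal screen of intestinal organoids: spherical
epithelial shells (bright in the F-actin channel) around a central lumen,
with nuclei rendered as small bright blobs in the nuclei (Hoechst) channel.
A severity fraction ``theta`` in [0, 1] maps drug effect onto morphology:
radius shrinkage (up to 40%), lumen-fraction reduction, nucleus-count
reduction (up to 50%) and dead-cell debris. A Hill dose-occupancy model
turns concentration into theta, so simulated screens have a known EC50.

All randomness flows through explicit integer seeds; identical
(parameters, seed) yield bit-identical stacks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .core import AcquisitionParams, ImageStack, ValidationError

# intensity of the actin shell / nucleus blobs above background, in counts
ACTIN_SHELL_AMPLITUDE = 900.0
ACTIN_LUMEN_FRACTION = 0.08     # lumen interior relative to shell
ACTIN_CAP_FLOOR = 0.10          # polar-cap shell brightness floor
DAPI_NUCLEUS_AMPLITUDE = 1200.0
DAPI_CYTO_FRACTION = 0.04       # faint organoid body in the nuclei channel
NUCLEUS_RADIUS_UM = 6.0
DEBRIS_RADIUS_UM = 3.0
DEBRIS_AMPLITUDE = 500.0

# theta -> morphology effect sizes (linear interpolation at theta = 1)
RADIUS_SHRINKAGE_MAX = 0.40
LUMEN_REDUCTION_MAX = 0.60
NUCLEI_REDUCTION_MAX = 0.50
DEBRIS_PER_ORGANOID_MAX = 3.0


@dataclass(frozen=True)
class CompoundModel:
    """Hill dose-response parameters of one simulated compound."""

    name: str
    ec50: float       # nM
    hill: float = 1.0
    max_effect: float = 1.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValidationError("hill slope must be > 0")
        if not 0.0 <= self.max_effect <= 1.0:
            raise ValidationError("max_effect must lie in [0, 1]")


@dataclass(frozen=True)
class PhenotypeParams:
    """Baseline well morphology and the severity fraction theta."""

    theta: float = 0.0
    n_organoids: int = 8
    organoid_radius_mean: float = 60.0   # µm
    organoid_radius_sd: float = 8.0      # µm
    lumen_fraction: float = 0.55         # lumen radius / organoid radius
    nuclei_per_organoid_mean: float = 12.0
    debris_fraction: float = 0.5         # debris density scale, [0, 1]
    out_of_focus_fraction: float = 0.0   # fraction rendered defocused

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError("theta must lie in [0, 1]")
        if self.n_organoids < 0 or self.nuclei_per_organoid_mean < 0:
            raise ValidationError("counts must be >= 0")
        if self.organoid_radius_mean <= 0 or self.organoid_radius_sd < 0:
            raise ValidationError("radii must be > 0")
        if not 0.0 <= self.lumen_fraction < 1.0:
            raise ValidationError("lumen_fraction must lie in [0, 1)")
        if not 0.0 <= self.debris_fraction <= 1.0:
            raise ValidationError("debris_fraction must lie in [0, 1]")
        if not 0.0 <= self.out_of_focus_fraction <= 1.0:
            raise ValidationError("out_of_focus_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlateDesign:
    """Dilution-series plate layout: 9-point 2-fold series, 8 replicates."""

    n_doses: int = 9
    dilution_factor: float = 2.0
    top_dose: float = 50.0        # nM
    n_replicates: int = 8
    n_control_wells: int = 8
    control_label: str = "DMSO"

    def __post_init__(self):
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")
        if self.dilution_factor <= 1:
            raise ValidationError("dilution_factor must be > 1")
        if self.top_dose <= 0:
            raise ValidationError("top_dose must be > 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.n_control_wells < 1:
            raise ValidationError("n_control_wells must be >= 1")


GROUND_TRUTH_COLUMNS = [
    "well", "organoid_id", "x", "y", "z",
    "radius_um", "lumen_radius_um", "n_nuclei", "in_focus", "theta",
]

PLATE_ROWS = "ABCDEFGHIJKLMNOP"   # 384-well: 16 rows x 24 columns
PLATE_CAPACITY = 384


def dose_series(design: PlateDesign) -> List[float]:
    """Descending serial-dilution concentrations (nM) of a plate design.

    A 9-point 2-fold series from 50 nM ends at 50/2^8 ≈ 0.195 nM.
    """
    if design.n_doses < 1:
        raise ValidationError("n_doses must be >= 1")
    return [design.top_dose / design.dilution_factor ** i
            for i in range(design.n_doses)]


def hill_phenotype(dose: float, compound: CompoundModel) -> float:
    """Map a concentration to the severity fraction theta via a Hill curve.

    theta = max_effect * d^n / (d^n + EC50^n); monotone non-decreasing in
    dose, 0 at dose 0 and max_effect/2 at the EC50.
    """
    if dose < 0:
        raise ValidationError("dose must be >= 0")
    if dose == 0:
        return 0.0
    # work in log space for numeric range safety
    r = (compound.ec50 / dose) ** compound.hill
    return compound.max_effect / (1.0 + r)


def _effective_morphology(pheno: PhenotypeParams) -> Tuple[float, float, float]:
    """Theta-adjusted (radius mean, lumen fraction, nuclei mean)."""
    t = pheno.theta
    radius = pheno.organoid_radius_mean * (1.0 - RADIUS_SHRINKAGE_MAX * t)
    lumen = pheno.lumen_fraction * (1.0 - LUMEN_REDUCTION_MAX * t)
    nuclei = pheno.nuclei_per_organoid_mean * (1.0 - NUCLEI_REDUCTION_MAX * t)
    return radius, lumen, nuclei


def sample_organoid_records(pheno: PhenotypeParams, acq: AcquisitionParams,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-organoid geometry (centres, radii, lumens, nuclei counts).

    Centres are rejection-sampled so organoids neither overlap nor touch the
    frame border; raises if the frame cannot hold an organoid.
    """
    h, w = acq.frame_shape
    px = acq.pixel_size
    radius_mean, lumen_frac, nuclei_mean = _effective_morphology(pheno)

    records = []
    placed: List[Tuple[float, float, float]] = []   # (y_px, x_px, r_px)
    for oid in range(1, pheno.n_organoids + 1):
        r_um = float(np.clip(
            rng.normal(radius_mean, pheno.organoid_radius_sd),
            0.4 * radius_mean, 1.8 * radius_mean))
        r_px = r_um / px
        margin = r_px + 3.0
        if 2 * margin >= min(h, w):
            raise ValidationError(
                f"frame {acq.frame_shape} too small for organoid radius "
                f"{r_um:.0f} µm at {px} µm/px")
        for _ in range(200):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - py) ** 2 + (x - px2) ** 2 > (r_px + pr + 3.0) ** 2
                   for py, px2, pr in placed):
                break
        else:
            # field is crowded; skip this organoid rather than overlap
            continue
        placed.append((y, x, r_px))
        z_margin = min(r_um, acq.depth_um / 2.0)
        z_um = rng.uniform(z_margin, acq.depth_um - z_margin)
        n_nuc = int(rng.poisson(nuclei_mean)) if nuclei_mean > 0 else 0
        in_focus = bool(rng.uniform() >= pheno.out_of_focus_fraction)
        records.append({
            "organoid_id": oid, "x": x, "y": y, "z": z_um / acq.z_step,
            "radius_um": r_um, "lumen_radius_um": lumen_frac * r_um,
            "n_nuclei": n_nuc, "in_focus": in_focus, "theta": pheno.theta,
        })
    return pd.DataFrame(records, columns=[c for c in GROUND_TRUTH_COLUMNS
                                          if c != "well"])


def _add_blob(volume: np.ndarray, zc: float, yc: float, xc: float,
              sigma_z: float, sigma_xy: float, amplitude: float) -> None:
    """Add a separable Gaussian blob to a (z, y, x) volume in place."""
    nz, h, w = volume.shape
    z = np.arange(nz)
    gz = np.exp(-0.5 * ((z - zc) / max(sigma_z, 1e-6)) ** 2)
    y0, y1 = max(0, int(yc - 4 * sigma_xy)), min(h, int(yc + 4 * sigma_xy) + 1)
    x0, x1 = max(0, int(xc - 4 * sigma_xy)), min(w, int(xc + 4 * sigma_xy) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)
    xx = np.arange(x0, x1)
    gy = np.exp(-0.5 * ((yy - yc) / sigma_xy) ** 2)
    gx = np.exp(-0.5 * ((xx - xc) / sigma_xy) ** 2)
    patch = amplitude * gy[:, None] * gx[None, :]
    keep = gz > 1e-3
    volume[keep, y0:y1, x0:x1] += gz[keep, None, None] * patch[None]


def render_organoids(records: pd.DataFrame, acq: AcquisitionParams,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Render noise-free actin and nuclei signal volumes from geometry rows.

    Separated from :func:`generate_well_stack` so tests can construct exact
    fixtures (touching organoids, chosen nucleus counts) deterministically.
    """
    nz, (h, w) = acq.n_z_planes, acq.frame_shape
    actin = np.zeros((nz, h, w), dtype=np.float64)
    dapi = np.zeros((nz, h, w), dtype=np.float64)
    px = acq.pixel_size
    nuc_sigma_px = NUCLEUS_RADIUS_UM / px / 1.5
    nuc_sigma_z = NUCLEUS_RADIUS_UM / acq.z_step

    for row in records.itertuples(index=False):
        r_px = row.radius_um / px
        lum_px = row.lumen_radius_um / px
        zc_planes = row.z
        r_planes = row.radius_um / acq.z_step
        y0 = max(0, int(row.y - r_px - 2))
        y1 = min(h, int(row.y + r_px + 3))
        x0 = max(0, int(row.x - r_px - 2))
        x1 = min(w, int(row.x + r_px + 3))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - row.y) ** 2 + (xx - row.x) ** 2

        if row.in_focus:
            planes = range(max(0, int(np.floor(zc_planes - r_planes))),
                           min(nz, int(np.ceil(zc_planes + r_planes)) + 1))
            for k in planes:
                dz = (k - zc_planes) * acq.z_step / row.radius_um
                if abs(dz) >= 1.0:
                    continue
                rp = r_px * np.sqrt(1.0 - dz * dz)
                lum_3d = (row.lumen_radius_um / px)
                lp2 = lum_3d ** 2 - (dz * r_px) ** 2
                rp_l = np.sqrt(lp2) if lp2 > 0 else 0.0
                disc = d2 <= rp * rp
                lumen = d2 <= rp_l * rp_l
                shell = disc & ~lumen
                # polarized cortical actin: the membrane running parallel to
                # the optical axis (the annulus outside the lumen footprint)
                # is bright; the apical caps directly above/below the lumen
                # are dim, so the max projection keeps a dark lumen the way
                # phalloidin-stained epithelial shells do
                over_lumen = d2 < lum_px * lum_px
                weight = np.where(over_lumen, ACTIN_CAP_FLOOR, 1.0)
                patch = np.zeros_like(weight)
                patch[shell] = ACTIN_SHELL_AMPLITUDE * weight[shell]
                patch[lumen] = ACTIN_SHELL_AMPLITUDE * ACTIN_LUMEN_FRACTION
                actin[k, y0:y1, x0:x1] += patch
                dapi[k, y0:y1, x0:x1][disc] += (
                    DAPI_NUCLEUS_AMPLITUDE * DAPI_CYTO_FRACTION)
        else:
            # defocused object: collapse the projected shell into the
            # nearest end plane and blur heavily -> low Laplacian variance
            k = 0 if zc_planes < nz / 2 else nz - 1
            disc = d2 <= r_px * r_px
            lumen = d2 <= lum_px * lum_px
            patch = np.zeros((y1 - y0, x1 - x0))
            patch[disc & ~lumen] = ACTIN_SHELL_AMPLITUDE * 0.7
            patch[lumen] = ACTIN_SHELL_AMPLITUDE * ACTIN_LUMEN_FRACTION * 0.7
            patch = ndimage.gaussian_filter(patch, 6.0)
            actin[k, y0:y1, x0:x1] += patch
            dapi[k, y0:y1, x0:x1] += patch * 0.2

        # nuclei sit on the epithelial shell
        n_nuc = int(row.n_nuclei)
        if n_nuc > 0:
            shell_lo = max(row.lumen_radius_um / row.radius_um, 0.55)
            frac = rng.uniform(shell_lo, 0.92, size=n_nuc)
            costh = rng.uniform(-1, 1, size=n_nuc)
            phi = rng.uniform(0, 2 * np.pi, size=n_nuc)
            sinth = np.sqrt(1 - costh ** 2)
            nx = row.x + frac * row.radius_um / px * sinth * np.cos(phi)
            ny = row.y + frac * row.radius_um / px * sinth * np.sin(phi)
            nzc = row.z + frac * row.radius_um / acq.z_step * costh
            target = dapi if row.in_focus else None
            for j in range(n_nuc):
                if target is None:
                    # defocused organoid: smear nuclei into its end plane
                    k = 0 if zc_planes < nz / 2 else nz - 1
                    _add_blob(dapi, k, ny[j], nx[j], 0.5,
                              nuc_sigma_px * 3, DAPI_NUCLEUS_AMPLITUDE * 0.1)
                else:
                    _add_blob(dapi, nzc[j], ny[j], nx[j], nuc_sigma_z,
                              nuc_sigma_px, DAPI_NUCLEUS_AMPLITUDE)
    return actin, dapi


def _apply_noise(signal: np.ndarray, acq: AcquisitionParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on signal + Gaussian background, as uint16."""
    scaled = np.clip(signal, 0, None) * acq.photon_scaling
    shot = rng.poisson(scaled).astype(np.float64) / acq.photon_scaling
    out = shot + acq.background_level + rng.normal(
        0.0, acq.noise_sd, size=signal.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def generate_well_stack(pheno: PhenotypeParams, acq: AcquisitionParams,
                        seed: int, well_id: str = "well",
                        ) -> Tuple[ImageStack, pd.DataFrame]:
    """Render one well: a two-channel stack plus its ground-truth table.

    Returns the stack and a DataFrame with one row per rendered organoid
    (centre in pixels/planes, radii in µm, nucleus count, in-focus flag,
    theta). ``n_organoids=0`` yields pure background noise and an empty
    table. Identical (parameters, seed) give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    records = sample_organoid_records(pheno, acq, rng)
    actin, dapi = render_organoids(records, acq, rng)

    # dose-dependent dead-cell debris: small bright specks in both channels
    n_debris = int(rng.poisson(DEBRIS_PER_ORGANOID_MAX * pheno.debris_fraction
                               * pheno.theta * max(pheno.n_organoids, 1)))
    h, w = acq.frame_shape
    for _ in range(n_debris):
        dy, dx = rng.uniform(3, h - 3), rng.uniform(3, w - 3)
        dz = rng.uniform(0, acq.n_z_planes - 1)
        s = DEBRIS_RADIUS_UM / acq.pixel_size
        _add_blob(actin, dz, dy, dx, 0.8, s, DEBRIS_AMPLITUDE)
        _add_blob(dapi, dz, dy, dx, 0.8, s, DEBRIS_AMPLITUDE * 0.8)

    # mild optical blur before noise
    for vol in (actin, dapi):
        for k in range(vol.shape[0]):
            if vol[k].any():
                vol[k] = ndimage.gaussian_filter(vol[k], 1.0)

    stack = ImageStack(
        nuclei_channel=_apply_noise(dapi, acq, rng),
        actin_channel=_apply_noise(actin, acq, rng),
        acquisition=acq, well_id=well_id)
    gt = records.copy()
    gt.insert(0, "well", well_id)
    return stack, gt


def well_seed(master_seed: int, well_id: str) -> int:
    """Deterministic per-well seed below 2^31 derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{well_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _well_name(index: int) -> str:
    row, col = divmod(index, 24)
    return f"{PLATE_ROWS[row]}{col + 1:02d}"


def build_layout(design: PlateDesign, compounds: Sequence[CompoundModel],
                 top_doses: Optional[Dict[str, float]] = None) -> pd.DataFrame:
    """Plate layout: control wells first, then one row per treated well."""
    total = design.n_control_wells + (len(compounds) * design.n_doses
                                      * design.n_replicates)
    if total > PLATE_CAPACITY:
        raise ValidationError(
            f"{total} wells exceed the {PLATE_CAPACITY}-well plate capacity")
    rows = []
    idx = 0
    for rep in range(design.n_control_wells):
        rows.append({"well": _well_name(idx), "compound": design.control_label,
                     "dose_nM": 0.0, "role": "control", "replicate": rep + 1})
        idx += 1
    for comp in compounds:
        top = (top_doses or {}).get(comp.name, design.top_dose)
        doses = dose_series(PlateDesign(
            n_doses=design.n_doses, dilution_factor=design.dilution_factor,
            top_dose=top, n_replicates=design.n_replicates,
            n_control_wells=design.n_control_wells,
            control_label=design.control_label))
        for dose in doses:
            for rep in range(design.n_replicates):
                rows.append({"well": _well_name(idx), "compound": comp.name,
                             "dose_nM": dose, "role": "treated",
                             "replicate": rep + 1})
                idx += 1
    return pd.DataFrame(rows)


def generate_screen(design: PlateDesign, compounds: Sequence[CompoundModel],
                    base_pheno: PhenotypeParams, acq: AcquisitionParams,
                    seed: int, out_dir: Optional[str | Path] = None,
                    top_doses: Optional[Dict[str, float]] = None):
    """Simulate a full plate: one stack pair per well, layout + ground truth.

    Treated wells get theta = hill_phenotype(dose); controls theta = 0.
    With ``out_dir`` set, writes ``<well>_dapi.tif`` / ``<well>_actin.tif``
    (16-bit multi-page TIFF), ``layout.csv`` and ``ground_truth.csv`` and
    returns (layout, ground_truth, out_dir); otherwise returns
    (layout, ground_truth, dict well -> ImageStack) in memory.
    """
    layout = build_layout(design, compounds, top_doses)
    comp_by_name = {c.name: c for c in compounds}
    stacks: Dict[str, ImageStack] = {}
    gt_frames = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for row in layout.itertuples(index=False):
        if row.role == "control":
            theta = 0.0
        else:
            theta = hill_phenotype(row.dose_nM, comp_by_name[row.compound])
        pheno = PhenotypeParams(
            theta=theta, n_organoids=base_pheno.n_organoids,
            organoid_radius_mean=base_pheno.organoid_radius_mean,
            organoid_radius_sd=base_pheno.organoid_radius_sd,
            lumen_fraction=base_pheno.lumen_fraction,
            nuclei_per_organoid_mean=base_pheno.nuclei_per_organoid_mean,
            debris_fraction=base_pheno.debris_fraction,
            out_of_focus_fraction=base_pheno.out_of_focus_fraction)
        stack, gt = generate_well_stack(
            pheno, acq, well_seed(seed, row.well), well_id=row.well)
        gt_frames.append(gt)
        if out_path is not None:
            tifffile.imwrite(out_path / f"{row.well}_dapi.tif",
                             stack.nuclei_channel)
            tifffile.imwrite(out_path / f"{row.well}_actin.tif",
                             stack.actin_channel)
        else:
            stacks[row.well] = stack

    ground_truth = (pd.concat(gt_frames, ignore_index=True) if gt_frames
                    else pd.DataFrame(columns=GROUND_TRUTH_COLUMNS))
    if out_path is not None:
        layout.to_csv(out_path / "layout.csv", index=False)
        ground_truth.to_csv(out_path / "ground_truth.csv", index=False)
        return layout, ground_truth, out_path
    return layout, ground_truth, stacks


def load_well_stack(plate_dir: str | Path, well_id: str,
                    acq: AcquisitionParams) -> ImageStack:
    """Read one well's TIFF stack pair written by :func:`generate_screen`."""
    plate_dir = Path(plate_dir)
    dapi = tifffile.imread(plate_dir / f"{well_id}_dapi.tif")
    actin = tifffile.imread(plate_dir / f"{well_id}_actin.tif")
    return ImageStack(nuclei_channel=np.asarray(dapi),
                      actin_channel=np.asarray(actin),
                      acquisition=acq, well_id=well_id)


def acquisition_to_dict(acq: AcquisitionParams) -> dict:
    d = asdict(acq)
    d["frame_shape"] = list(acq.frame_shape)
    return d
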