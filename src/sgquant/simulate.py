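"""Synthetic multi-channel fluorescence fields and screen plates with planted truth.

Emulates the assay this pipeline quantifies: adherent glioblastoma-like cells
(one nucleus each) stained with DAPI (nuclei), wheat-germ agglutinin (membrane
ridges at cell borders) and two cytoplasmic stress-granule markers (e.g. TIAR
and G3BP2).  Every generated object is recorded as ground truth so that
segmentation, puncta detection, dual-marker calling and screen scoring can be
benchmarked without external data.

The per-cell punctum model: each cell draws a negative-binomial number ``N`` of
punctum *sites* (mean ``mu``, dispersion ``k``, variance ``mu + mu**2/k``).
Each site is dual-channel ("both") with probability ``rho`` — rendered at the
same location in both marker channels with independently jittered amplitudes —
otherwise it contributes one marker1-only and one marker2-only punctum at
independent locations.  Each channel therefore carries exactly ``N`` puncta of
which a Binomial(N, rho) subset coincides, so the expected coincident fraction
of either channel's puncta is ``rho`` and per-channel counts remain NB(mu, k).
A cell's true stress-granule count is its number of "both" sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldSpec",
    "PlateSpec",
    "GroundTruth",
    "generate_field",
    "generate_screen_plate",
    "save_field",
    "save_ground_truth",
    "save_plate",
]

CHANNEL_ROLES = ("nuclei", "membrane", "marker1", "marker2")

#: channel-presence codes for a punctum site
PRESENCE_BOTH = "both"
PRESENCE_M1 = "marker1-only"
PRESENCE_M2 = "marker2-only"


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated field of view.

    ``snr`` is the peak punctum/nucleus amplitude divided by the total
    background noise SD (read noise plus Poisson shot noise at the background
    level).  ``coincidence_fraction`` is the probability that a punctum site is
    rendered in both marker channels.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 60
    nucleus_radius_range: tuple[float, float] = (6.0, 9.0)
    cell_radius_range: tuple[float, float] = (16.0, 24.0)
    puncta_per_cell_mean: float = 5.0
    puncta_dispersion: float = 2.0
    coincidence_fraction: float = 0.6
    punctum_sigma: float = 1.2
    snr: float = 10.0
    background_level: float = 100.0
    noise_sigma: float = 5.0
    seed: int = 0
    #: exact puncta count per cell instead of the NB draw (fixture use)
    fixed_puncta_per_cell: int | None = None
    #: minimum center-to-center distance between a cell's puncta (0 = none)
    min_punctum_separation: float = 0.0
    #: keep punctum centers this far inside the cytoplasm boundary, so the
    #: rendered granule (an extended object ~2 sigma wide) lies wholly within
    #: its compartment
    punctum_margin: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coincidence_fraction <= 1.0):
            raise ValueError("coincidence_fraction must lie in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        rn = self.nucleus_radius_range
        rc = self.cell_radius_range
        if min(rn) <= 0 or min(rc) <= 0:
            raise ValueError("radii must be positive")
        if max(rn) >= min(rc):
            raise ValueError("nucleus radii must be smaller than cell radii")
        if self.puncta_dispersion <= 0:
            raise ValueError("puncta_dispersion must be positive")
        if self.width < 32 or self.height < 32:
            raise ValueError("field must be at least 32x32 pixels")

    @property
    def background_noise_sd(self) -> float:
        """Total background noise SD: Gaussian read noise + Poisson shot noise."""
        return float(np.sqrt(self.noise_sigma**2 + self.background_level))

    @property
    def peak_amplitude(self) -> float:
        return self.snr * self.background_noise_sd


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of one simulated screen plate (drug wells plus controls)."""

    n_drugs: int = 1120
    n_control_wells: int = 96
    control_mean: float = 1.0
    control_sd: float = 0.25
    hit_indices: frozenset[int] = frozenset()
    hit_effect: float = 4.0
    normoxia_inducer_indices: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hit_indices", frozenset(self.hit_indices))
        object.__setattr__(
            self, "normoxia_inducer_indices", frozenset(self.normoxia_inducer_indices)
        )
        if self.hit_effect < 0:
            raise ValueError("hit_effect must be >= 0")
        if self.control_sd < 0:
            raise ValueError("control_sd must be >= 0")
        valid = range(1, self.n_drugs + 1)
        for idx_set, name in (
            (self.hit_indices, "hit_indices"),
            (self.normoxia_inducer_indices, "normoxia_inducer_indices"),
        ):
            if not all(i in valid for i in idx_set):
                raise ValueError(f"{name} must be within 1..n_drugs")


@dataclass
class GroundTruth:
    """Planted truth for one field.

    ``nuclei``/``cells`` are per-object tables; ``puncta`` has one row per
    rendered punctum site with its channel presence.  A cell's true SG count is
    its number of ``"both"`` sites.
    """

    nuclei: pd.DataFrame  # label, row, col, radius
    cells: pd.DataFrame  # label, row, col (nucleus center), cell_radius, true_sg_count, touches_border
    puncta: pd.DataFrame  # cell_label, row, col, amplitude_m1, amplitude_m2, presence
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray

    @property
    def true_sg_counts(self) -> pd.Series:
        return self.cells.set_index("label")["true_sg_count"]


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: adding wells/fields never perturbs earlier ones."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Rejection-sample nucleus centers with minimum separation.

    Separation is 90% of the sum of the two cells' radii, so neighbouring cell
    territories touch (sharing a membrane ridge) but nuclei stay far apart.
    """
    centers: list[tuple[float, float]] = []
    nuc_r: list[float] = []
    cell_r: list[float] = []
    margin = max(spec.nucleus_radius_range) + 2.0
    max_attempts = 2000 * spec.n_cells
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot place {spec.n_cells} cells in a {spec.height}x{spec.width} "
                f"field (placed {len(centers)}); reduce n_cells or cell radii"
            )
        attempts += 1
        r = rng.uniform(margin, spec.height - margin)
        c = rng.uniform(margin, spec.width - margin)
        rn = rng.uniform(*spec.nucleus_radius_range)
        rc = rng.uniform(*spec.cell_radius_range)
        ok = True
        for (r0, c0), rc0 in zip(centers, cell_r):
            if np.hypot(r - r0, c - c0) < 0.9 * (rc + rc0):
                ok = False
                break
        if ok:
            centers.append((r, c))
            nuc_r.append(rn)
            cell_r.append(rc)
    return np.asarray(centers), np.asarray(nuc_r), np.asarray(cell_r)


def _territories(spec: FieldSpec, centers, nuc_r, cell_r):
    """Distance-based cell partition: nearest nucleus scaled by jittered radius.

    A pixel belongs to the cell minimizing dist/radius, provided dist <= radius;
    nucleus disks always belong to their own cell.
    """
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w]
    best_ratio = np.full((h, w), np.inf)
    cell_lab = np.zeros((h, w), dtype=np.int32)
    for i, ((r0, c0), rc) in enumerate(zip(centers, cell_r), start=1):
        d = np.hypot(rr - r0, cc - c0)
        ratio = np.where(d <= rc, d / rc, np.inf)
        take = ratio < best_ratio
        best_ratio[take] = ratio[take]
        cell_lab[take] = i
    nuc_lab = np.zeros((h, w), dtype=np.int32)
    for i, ((r0, c0), rn) in enumerate(zip(centers, nuc_r), start=1):
        d = np.hypot(rr - r0, cc - c0)
        inside = d <= rn
        nuc_lab[inside] = i
        cell_lab[inside] = i  # nucleus always inside its own cell
    return nuc_lab, cell_lab


def _draw_puncta(spec: FieldSpec, cell_lab, nuc_lab, rng: np.random.Generator):
    """Place punctum sites uniformly in each cell's cytoplasm."""
    records = []
    n_labels = int(cell_lab.max())
    cyto = (cell_lab > 0) & (nuc_lab == 0)
    mu, k, rho = spec.puncta_per_cell_mean, spec.puncta_dispersion, spec.coincidence_fraction
    from scipy import ndimage

    for lab in range(1, n_labels + 1):
        mask = (cell_lab == lab) & cyto
        if spec.punctum_margin > 0 and mask.any():
            rows, cols = np.nonzero(mask)
            r0, r1 = rows.min(), rows.max() + 1
            c0, c1 = cols.min(), cols.max() + 1
            local = np.pad(mask[r0:r1, c0:c1], 1)
            inner = ndimage.distance_transform_edt(local) >= spec.punctum_margin
            eroded = np.zeros_like(mask)
            eroded[r0:r1, c0:c1] = inner[1:-1, 1:-1]
            if eroded.any():
                mask = eroded
        pix = np.flatnonzero(mask.ravel())
        if pix.size == 0:
            continue
        if spec.fixed_puncta_per_cell is not None:
            n_sites = spec.fixed_puncta_per_cell
        else:
            # NB(mu, k) as gamma-Poisson mixture
            lam = rng.gamma(shape=k, scale=mu / k)
            n_sites = rng.poisson(lam)
        placed: list[tuple[float, float]] = []

        def _pick() -> tuple[float, float]:
            for _ in range(200):
                idx = rng.choice(pix)
                r, c = divmod(int(idx), spec.width)
                jr, jc = rng.uniform(-0.5, 0.5, size=2)
                r, c = r + jr, c + jc
                if spec.min_punctum_separation <= 0 or all(
                    np.hypot(r - r0, c - c0) >= spec.min_punctum_separation
                    for r0, c0 in placed
                ):
                    placed.append((r, c))
                    return r, c
            # separation unattainable in this cytoplasm; fall back to last draw
            placed.append((r, c))
            return r, c

        for _ in range(n_sites):
            both = rng.random() < rho
            if both:
                r, c = _pick()
                a1 = spec.peak_amplitude * (1 + rng.uniform(-0.1, 0.1))
                a2 = spec.peak_amplitude * (1 + rng.uniform(-0.1, 0.1))
                records.append((lab, r, c, a1, a2, PRESENCE_BOTH))
            else:
                for presence in (PRESENCE_M1, PRESENCE_M2):
                    r, c = _pick()
                    a = spec.peak_amplitude * (1 + rng.uniform(-0.1, 0.1))
                    a1 = a if presence == PRESENCE_M1 else 0.0
                    a2 = a if presence == PRESENCE_M2 else 0.0
                    records.append((lab, r, c, a1, a2, presence))
    return pd.DataFrame(
        records,
        columns=["cell_label", "row", "col", "amplitude_m1", "amplitude_m2", "presence"],
    )


def _render_spots(shape, puncta: pd.DataFrame, amp_col: str, sigma: float) -> np.ndarray:
    """Sum of Gaussian spots, each rendered on a local window (4 sigma)."""
    img = np.zeros(shape, dtype=np.float64)
    half = max(3, int(np.ceil(4 * sigma)))
    h, w = shape
    for row in puncta.itertuples(index=False):
        a = getattr(row, amp_col)
        if a <= 0:
            continue
        r0, c0 = row.row, row.col
        rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += a * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
        )
    return img


def _add_noise(signal: np.ndarray, spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on the (background + signal) photon flux plus Gaussian
    read noise."""
    flux = np.clip(signal + spec.background_level, 0, None)
    shot = rng.poisson(flux).astype(np.float64)
    read = rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    return np.clip(shot + read, 0, None)


def generate_field(spec: FieldSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render one field: four float64 channel images keyed by role, plus truth.

    Deterministic: an identical ``FieldSpec`` (including seed) yields
    bit-identical images and ground truth.
    """
    rng_geom = _substream(spec.seed, 0)
    rng_puncta = _substream(spec.seed, 1)
    rng_noise = _substream(spec.seed, 2)

    centers, nuc_r, cell_r = _place_nuclei(spec, rng_geom)
    nuc_lab, cell_lab = _territories(spec, centers, nuc_r, cell_r)
    puncta = _draw_puncta(spec, cell_lab, nuc_lab, rng_puncta)

    amp = spec.peak_amplitude
    from scipy import ndimage
    from skimage.segmentation import find_boundaries

    # nuclei channel: soft-edged bright disks
    nuclei_sig = ndimage.gaussian_filter((nuc_lab > 0).astype(np.float64), 1.0) * amp

    # membrane channel: 2-px ridge at cell borders over dim cytoplasmic haze
    ridge = find_boundaries(cell_lab, mode="thick") & (cell_lab > 0)
    membrane_sig = (
        ndimage.gaussian_filter(ridge.astype(np.float64), 0.8) * amp
        + 0.35 * amp * ndimage.gaussian_filter((cell_lab > 0).astype(np.float64), 1.0)
    )

    m1_sig = _render_spots((spec.height, spec.width), puncta, "amplitude_m1", spec.punctum_sigma)
    m2_sig = _render_spots((spec.height, spec.width), puncta, "amplitude_m2", spec.punctum_sigma)

    channels = {
        "nuclei": _add_noise(nuclei_sig, spec, rng_noise),
        "membrane": _add_noise(membrane_sig, spec, rng_noise),
        "marker1": _add_noise(m1_sig, spec, rng_noise),
        "marker2": _add_noise(m2_sig, spec, rng_noise),
    }

    labels = np.arange(1, len(centers) + 1)
    touches = []
    for lab in labels:
        mask = cell_lab == lab
        touches.append(
            bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())
        )
    sg_counts = (
        puncta[puncta["presence"] == PRESENCE_BOTH].groupby("cell_label").size()
        if len(puncta)
        else pd.Series(dtype=int)
    )
    gt = GroundTruth(
        nuclei=pd.DataFrame(
            {"label": labels, "row": centers[:, 0], "col": centers[:, 1], "radius": nuc_r}
        ),
        cells=pd.DataFrame(
            {
                "label": labels,
                "row": centers[:, 0],
                "col": centers[:, 1],
                "cell_radius": cell_r,
                "true_sg_count": [int(sg_counts.get(lab, 0)) for lab in labels],
                "touches_border": touches,
            }
        ),
        puncta=puncta,
        nuclei_labels=nuc_lab,
        cell_labels=cell_lab,
    )
    return channels, gt


def generate_screen_plate(spec: PlateSpec, arm: str = "hypoxia-recovery") -> pd.DataFrame:
    """One plate arm as a well table.

    Columns: well_id, kind (drug|control), arm, mean_granules_per_cell,
    is_true_hit, is_normoxia_inducer.  In the hypoxia-recovery arm, hit wells
    and normoxia inducers are shifted up by ``hit_effect * control_sd`` (both
    retain granules after the stress); in the normoxia arm only the inducers
    are shifted (they form granules without stress).
    """
    if arm not in ("hypoxia-recovery", "normoxia"):
        raise ValueError(f"unknown arm {arm!r}")
    arm_key = 0 if arm == "hypoxia-recovery" else 1
    rows = []
    for i in range(1, spec.n_control_wells + 1):
        rng = _substream(spec.seed, arm_key, 0, i)
        x = rng.normal(spec.control_mean, spec.control_sd)
        rows.append((f"C{i:04d}", "control", arm, x, False, False))
    delta = spec.hit_effect * spec.control_sd
    for i in range(1, spec.n_drugs + 1):
        rng = _substream(spec.seed, arm_key, 1, i)
        x = rng.normal(spec.control_mean, spec.control_sd)
        is_hit = i in spec.hit_indices
        is_inducer = i in spec.normoxia_inducer_indices
        if arm == "hypoxia-recovery" and (is_hit or is_inducer):
            x += delta
        if arm == "normoxia" and is_inducer:
            x += delta
        rows.append((f"D{i:04d}", "drug", arm, x, is_hit, is_inducer))
    return pd.DataFrame(
        rows,
        columns=[
            "well_id",
            "kind",
            "arm",
            "mean_granules_per_cell",
            "is_true_hit",
            "is_normoxia_inducer",
        ],
    )


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def save_field(channels: dict[str, np.ndarray], outdir: str | Path, field_id: str) -> dict[str, Path]:
    """Write one 16-bit grayscale TIFF per channel, named ``<field>_<role>.tif``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role in CHANNEL_ROLES:
        p = outdir / f"{field_id}_{role}.tif"
        tifffile.imwrite(p, _to_uint16(channels[role]))
        paths[role] = p
    return paths


def save_ground_truth(gt: GroundTruth, outdir: str | Path, field_id: str) -> None:
    """Write truth tables as CSV and label masks as 16-bit TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.nuclei.to_csv(outdir / f"{field_id}_nuclei.csv", index=False)
    gt.cells.to_csv(outdir / f"{field_id}_cells.csv", index=False)
    gt.puncta.to_csv(outdir / f"{field_id}_puncta.csv", index=False)
    tifffile.imwrite(outdir / f"{field_id}_nuclei_labels.tif", gt.nuclei_labels.astype(np.uint16))
    tifffile.imwrite(outdir / f"{field_id}_cell_labels.tif", gt.cell_labels.astype(np.uint16))


def save_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)
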