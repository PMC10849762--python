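"""Seeded synthetic inputs for every stage of the invasion-analysis pipeline.

Three generators mirror the data the pipeline consumes:

* :func:`simulate_screen_counts` — guide-level counts from a pooled CRISPR
  knockout screen read out in a paired core / invasive selection, with a
  planted subset of invasion-essential genes depleted in the invasive
  fraction.
* :func:`simulate_mask` — calibrated binary masks: analytic validation
  shapes (disk, line, filled square, Sierpinski carpet), stochastic
  branched-growth tumours of tunable boundary complexity, and cell fields
  emulating spheroid and channel-device invasion assays.
* :func:`simulate_paired_abundance` — log-normal feature-abundance matrices
  over paired core/invasive samples with a fraction of truly changed
  features.

Every generator takes an explicit seed and is bit-reproducible; planted
truth labels are returned alongside the data (never embedded in it) so
downstream recovery can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimConfig",
    "MaskSimConfig",
    "AbundanceSimConfig",
    "simulate_screen_counts",
    "simulate_mask",
    "simulate_paired_abundance",
    "write_counts_tsv",
    "write_abundance_tsv",
    "write_mask",
]

NONTARGETING_GENE = "NTC"

#: log-SD of the log-normal guide baseline abundances (library skew).
BASELINE_LOG_SD = 0.5


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration for the pooled-screen count generator.

    Defaults mirror a metabolism-focused knockout library read out from six
    hydrogel invasion devices: 2,981 genes x 10 guides plus 1,000
    nontargeting controls, counts drawn negative-binomially
    (``var = mu + mu^2 * dispersion``) around log-normal guide baselines.
    ``effect_log2`` is the planted log2 shift applied to invasive-fraction
    means of essential-gene guides; negative means depleted among invaders,
    i.e. the knockout disrupted invasion.
    """

    n_genes: int = 2981
    guides_per_gene: int = 10
    n_nontargeting: int = 1000
    frac_essential: float = 0.05
    effect_log2: float = -2.0
    dispersion: float = 0.2
    mean_depth: float = 500.0
    n_core_samples: int = 3
    n_invasive_samples: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.n_core_samples,
               self.n_invasive_samples) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_nontargeting < 0:
            raise ValueError("n_nontargeting must be >= 0")
        if not 0.0 <= self.frac_essential <= 1.0:
            raise ValueError("frac_essential must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


@dataclass(frozen=True)
class MaskSimConfig:
    """Configuration for binary-mask generation.

    ``shape_kind`` selects the construction; the geometric parameters that
    apply depend on it (``radius`` for disks/spheroid cores, ``depth`` for
    the Sierpinski carpet, ``branch_intensity``/``n_branches`` for
    branched growth, ``n_cells`` and ``channel_edge_x_um`` for cell
    fields).  ``pixel_size_um`` calibrates pixels to micrometres.
    """

    shape_kind: str = "disk"
    image_size: int = 256
    pixel_size_um: float = 1.0
    radius: int = 50
    depth: int = 4
    branch_intensity: float = 1.0
    n_branches: int | None = None
    n_cells: int = 30
    cell_radius: int = 3
    detached_positions_um: Sequence[tuple[float, float]] = field(default_factory=tuple)
    channel_edge_x_um: float = 0.0
    seed: int = 0

    _KINDS = ("disk", "line", "filled_square", "sierpinski_carpet",
              "branched_growth", "spheroid_field", "device_field")

    def __post_init__(self) -> None:
        if self.shape_kind not in self._KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.image_size <= 0:
            raise ValueError("image_size must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class AbundanceSimConfig:
    """Configuration for the paired core/invasive abundance generator.

    Defaults follow a seven-pair hydrogel-device design profiling a few
    hundred features; changed features are shifted by ``effect_log2`` in
    the invasive member of every pair on top of log-normal noise with
    ``noise_sd_log`` (natural-log scale).
    """

    n_features: int = 500
    n_pairs: int = 7
    frac_changed: float = 0.05
    effect_log2: float = 3.0
    noise_sd_log: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.frac_changed <= 1.0:
            raise ValueError("frac_changed must lie in [0, 1]")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be > 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


# ---------------------------------------------------------------------------
# pooled screen
# ---------------------------------------------------------------------------

def _nbinom_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + mu^2 * dispersion."""
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_screen_counts(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate guide counts for a paired core/invasive pooled screen.

    Returns
    -------
    counts : DataFrame
        Columns ``guide_id, gene, is_nontargeting`` followed by one integer
        count column per sample (``core_1..``, ``invasive_1..``).
    truth : dict
        ``essential_genes`` (sorted list), ``expected_log2_shift`` per gene,
        and the config used.
    """
    rng = np.random.default_rng(cfg.seed)
    n_target = cfg.n_genes * cfg.guides_per_gene
    n_guides = n_target + cfg.n_nontargeting

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    gene_col = np.repeat(genes, cfg.guides_per_gene).tolist() + \
        [NONTARGETING_GENE] * cfg.n_nontargeting
    guide_ids = [f"{g}_sg{j % cfg.guides_per_gene}" for j, g in enumerate(gene_col[:n_target])]
    guide_ids += [f"NTC_sg{j}" for j in range(cfg.n_nontargeting)]
    is_ntc = np.r_[np.zeros(n_target, bool), np.ones(cfg.n_nontargeting, bool)]

    n_essential = int(round(cfg.frac_essential * cfg.n_genes))
    if n_essential == 0 and cfg.effect_log2 != 0 and cfg.frac_essential > 0:
        warnings.warn("frac_essential * n_genes < 1: no planted signal", stacklevel=2)
    essential_idx = rng.choice(cfg.n_genes, size=n_essential, replace=False)
    essential = sorted(genes[i] for i in essential_idx)
    essential_set = set(essential)

    # log-normal library skew around the target depth (mean-preserving)
    baseline = rng.lognormal(mean=-BASELINE_LOG_SD**2 / 2, sigma=BASELINE_LOG_SD,
                             size=n_guides)
    mu_core = cfg.mean_depth * baseline
    shift = np.array([2.0 ** cfg.effect_log2 if g in essential_set else 1.0
                      for g in gene_col])
    shift[is_ntc] = 1.0
    mu_inv = mu_core * shift

    data = {"guide_id": guide_ids, "gene": gene_col, "is_nontargeting": is_ntc}
    for r in range(cfg.n_core_samples):
        data[f"core_{r + 1}"] = _nbinom_draw(rng, mu_core, cfg.dispersion)
    for r in range(cfg.n_invasive_samples):
        data[f"invasive_{r + 1}"] = _nbinom_draw(rng, mu_inv, cfg.dispersion)

    truth = {
        "essential_genes": essential,
        "expected_log2_shift": {g: (cfg.effect_log2 if g in essential_set else 0.0)
                                for g in genes},
        "config": asdict(cfg),
    }
    return pd.DataFrame(data), truth


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _sierpinski_carpet(depth: int) -> np.ndarray:
    """Triadic carpet on a 3^depth grid; exactly 8^depth filled pixels."""
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    return m


def _disk(size: int, radius: int, center: tuple[float, float] | None = None) -> np.ndarray:
    c = (size / 2.0, size / 2.0) if center is None else center
    yy, xx = np.mgrid[:size, :size]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius ** 2


def _stamp_disk(mask: np.ndarray, cy: int, cx: int, radius: int) -> None:
    size = mask.shape[0]
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, size)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, size)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _branched_growth(cfg: MaskSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random branching walk from the image centre.

    The number of primary branches scales with ``branch_intensity``; each
    branch is a persistent random walk that may spawn children.  Higher
    intensity fills more of the plane, raising the box-counting dimension
    of the resulting outline toward 2.
    """
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=bool)
    center = (size // 2, size // 2)
    _stamp_disk(mask, *center, max(size // 20, 2))

    n_branches = cfg.n_branches
    if n_branches is None:
        n_branches = max(1, int(round(6 * cfg.branch_intensity)))
    max_len = int(size * 0.45)
    stack = [(float(center[0]), float(center[1]),
              rng.uniform(0, 2 * np.pi), max_len) for _ in range(n_branches)]
    p_branch = min(0.01 * cfg.branch_intensity, 0.1)
    max_segments = 40 * n_branches  # hard cap: keeps generation O(size^2)
    segments = 0
    while stack and segments < max_segments:
        y, x, theta, budget = stack.pop()
        segments += 1
        for _ in range(budget):
            theta += rng.normal(0, 0.25)
            y += np.sin(theta)
            x += np.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if not (1 <= iy < size - 1 and 1 <= ix < size - 1):
                break
            mask[iy - 1:iy + 2, ix - 1:ix + 2] = True  # 3x3 brush
            if rng.random() < p_branch and budget > 10:
                stack.append((y, x, theta + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2),
                              budget // 2))
    return mask


def _cell_field(cfg: MaskSimConfig, rng: np.random.Generator, device: bool) -> np.ndarray:
    """Spheroid or channel-device field: a connected core plus single cells.

    Background cells are laid down in close pairs (centroid gap under
    10 um at 1 um/px) so that none of them is "detached" under the
    nearest-neighbour rule; ``detached_positions_um`` pins isolated cells
    at exact coordinates (origin at image corner, x rightward, y downward),
    and a 30 um exclusion zone keeps background pairs away from them, so
    the distance-rule ground truth is exactly the pinned cells.
    """
    size = cfg.image_size
    px = cfg.pixel_size_um
    mask = np.zeros((size, size), dtype=bool)
    if device:
        # cell reservoir: solid band left of the channel edge
        edge_px = int(round(cfg.channel_edge_x_um / px))
        mask[:, :max(edge_px, 1)] = True
    else:
        mask |= _disk(size, cfg.radius)

    reserved_px = [(y_um / px, x_um / px) for (x_um, y_um) in cfg.detached_positions_um]

    def usable(cy: float, cx: float, placed: list[tuple[float, float]]) -> bool:
        lo, hi = cfg.cell_radius, size - cfg.cell_radius - 1
        if not (lo <= cy <= hi and lo <= cx <= hi):
            return False
        if mask[int(round(cy)), int(round(cx))]:
            return False
        if any((cy - ry) ** 2 + (cx - rx) ** 2 < (30.0 / px) ** 2
               for (ry, rx) in reserved_px):
            return False
        min_sep = 2 * cfg.cell_radius + 2
        return not any((cy - p[0]) ** 2 + (cx - p[1]) ** 2 < min_sep ** 2 for p in placed)

    placed: list[tuple[float, float]] = []
    pair_gap_px = 2 * cfg.cell_radius + 2  # touching-distance + 1 px gap
    for _ in range(max(cfg.n_cells // 2, 0)):
        for _attempt in range(300):
            cy = float(rng.integers(cfg.cell_radius, size - cfg.cell_radius))
            cx = float(rng.integers(cfg.cell_radius, size - cfg.cell_radius))
            theta = rng.uniform(0, 2 * np.pi)
            py = cy + pair_gap_px * np.sin(theta)
            px_ = cx + pair_gap_px * np.cos(theta)
            if usable(cy, cx, placed) and usable(py, px_, placed + [(cy, cx)]):
                _stamp_disk(mask, int(round(cy)), int(round(cx)), cfg.cell_radius)
                _stamp_disk(mask, int(round(py)), int(round(px_)), cfg.cell_radius)
                placed += [(cy, cx), (py, px_)]
                break
    for (ry, rx) in reserved_px:
        _stamp_disk(mask, int(round(ry)), int(round(rx)), cfg.cell_radius)
    return mask


def simulate_mask(cfg: MaskSimConfig) -> np.ndarray:
    """Generate a binary mask per ``cfg.shape_kind``.  See :class:`MaskSimConfig`."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    kind = cfg.shape_kind

    if kind == "sierpinski_carpet":
        side = 3 ** cfg.depth
        if side > size:
            raise ValueError(f"carpet of depth {cfg.depth} needs {side} px, image is {size}")
        carpet = _sierpinski_carpet(cfg.depth)
        mask = np.zeros((size, size), dtype=bool)
        mask[:side, :side] = carpet
        return mask
    if kind == "disk":
        if 2 * cfg.radius > size:
            raise ValueError("disk larger than image")
        return _disk(size, cfg.radius)
    if kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        return mask
    if kind == "filled_square":
        side = min(2 * cfg.radius, size)
        mask = np.zeros((size, size), dtype=bool)
        off = (size - side) // 2
        mask[off:off + side, off:off + side] = True
        return mask
    if kind == "branched_growth":
        return _branched_growth(cfg, rng)
    if kind == "spheroid_field":
        if 2 * cfg.radius > size:
            raise ValueError("spheroid core larger than image")
        return _cell_field(cfg, rng, device=False)
    if kind == "device_field":
        return _cell_field(cfg, rng, device=True)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# paired abundances
# ---------------------------------------------------------------------------

def simulate_paired_abundance(cfg: AbundanceSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a features x samples abundance matrix over core/invasive pairs.

    Returns ``(matrix, pairing, truth)``: the matrix has one row per feature
    and columns ``<unit>_core`` / ``<unit>_invasive``; ``pairing`` maps
    sample -> (unit, fraction); ``truth`` lists the changed features and the
    planted log2 effect.
    """
    rng = np.random.default_rng(cfg.seed)
    features = [f"F{i:04d}" for i in range(cfg.n_features)]
    n_changed = int(round(cfg.frac_changed * cfg.n_features))
    changed_idx = rng.choice(cfg.n_features, size=n_changed, replace=False)
    changed = np.zeros(cfg.n_features, dtype=bool)
    changed[changed_idx] = True

    base_log = rng.normal(loc=5.0, scale=1.0, size=cfg.n_features)  # ln-scale
    cols: dict[str, np.ndarray] = {}
    pairing_rows = []
    for u in range(cfg.n_pairs):
        unit = f"U{u + 1}"
        noise_c = rng.normal(0, cfg.noise_sd_log, cfg.n_features)
        noise_i = rng.normal(0, cfg.noise_sd_log, cfg.n_features)
        core = np.exp(base_log + noise_c)
        inv = np.exp(base_log + noise_i) * np.where(changed, 2.0 ** cfg.effect_log2, 1.0)
        cols[f"{unit}_core"] = core
        cols[f"{unit}_invasive"] = inv
        pairing_rows.append({"sample": f"{unit}_core", "unit": unit, "fraction": "core"})
        pairing_rows.append({"sample": f"{unit}_invasive", "unit": unit, "fraction": "invasive"})

    mat = pd.DataFrame(cols, index=pd.Index(features, name="feature"))
    pairing = pd.DataFrame(pairing_rows)
    truth = {
        "changed_features": sorted(np.array(features)[changed].tolist()),
        "effect_log2": cfg.effect_log2,
        "config": asdict(cfg),
    }
    return mat, pairing, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_abundance_tsv(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t")


def write_mask(mask: np.ndarray, path: str | Path,
               pixel_size_um: float = 1.0, channel_edge_x_um: float | None = None,
               timepoint_days: float | None = None) -> None:
    """Write an 8-bit mask image plus a JSON calibration sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
    sidecar = {"pixel_size_um": pixel_size_um}
    if channel_edge_x_um is not None:
        sidecar["channel_edge_x_um"] = channel_edge_x_um
    if timepoint_days is not None:
        sidecar["timepoint_days"] = timepoint_days
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
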