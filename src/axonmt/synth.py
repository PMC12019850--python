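"""Synthetic-data generators with known ground truth for every input class.

Each generator is a pure function of (parameters, seed): identical inputs
give identical outputs, and every generator returns a machine-readable ground
truth alongside the data so that downstream recovery tests can consume only
the data and compare against truth.

The FDAP presets embody the polymer fractions of untreated (0.81) and
peroxide-treated (0.70) axon-like processes; the absolute rate constants are
chosen in the slow-exchange regime resolvable at 1 frame/s.  Microtubule
arrays are worm-like chains layered ~70 nm apart axially, as in the layered
arrays of PC12 neurites; vesicle series mix run-and-pause directed motion
with stationary jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fdap import FDAPCurve, ReactionDiffusionParams, simulate_fdap
from .smlm import LocalizationTable
from .transport import DetectionTable

__all__ = [
    "FdapPreset",
    "FDAP_PRESETS",
    "ArrayModel",
    "MotilityModel",
    "gen_fdap",
    "gen_microtubule_array",
    "gen_vesicle_series",
    "gen_phospho_tables",
    "phospho_fixture",
]


# ---------------------------------------------------------------------------
# FDAP curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FdapPreset:
    """Named FDAP simulation condition with its acquisition schedule."""

    name: str
    params: ReactionDiffusionParams
    window_length_um: float = 6.0
    frame_interval_s: float = 1.0
    n_frames: int = 112


#: control: polymer fraction 0.81; h2o2: polymer fraction 0.70
FDAP_PRESETS: dict[str, FdapPreset] = {
    "control": FdapPreset("control", ReactionDiffusionParams(3.0, 0.081, 0.019)),
    "h2o2": FdapPreset("h2o2", ReactionDiffusionParams(3.0, 0.070, 0.030)),
}


def gen_fdap(
    preset: str | FdapPreset | ReactionDiffusionParams,
    n_curves: int = 20,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[FDAPCurve], pd.DataFrame]:
    """Simulate noisy FDAP curves and the generating truth table.

    Gaussian noise of the stated sd is added i.i.d. to the forward model and
    the curve re-normalized to its (noisy) first frame.  The truth table
    records the generating rates and bound fraction per curve.
    """
    if isinstance(preset, str):
        preset = FDAP_PRESETS[preset]
    if isinstance(preset, ReactionDiffusionParams):
        preset = FdapPreset("custom", preset)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = simulate_fdap(
        preset.params,
        window_length_um=preset.window_length_um,
        frame_interval_s=preset.frame_interval_s,
        n_frames=preset.n_frames,
    )
    curves = []
    rows = []
    for i in range(n_curves):
        intensity = clean.intensity + rng.normal(0.0, noise_sd, clean.intensity.size)
        intensity = np.clip(intensity, 1e-6, None)
        intensity = intensity / intensity[0]
        curves.append(
            FDAPCurve(
                clean.time_s.copy(),
                intensity,
                window_length_um=preset.window_length_um,
                frame_interval_s=preset.frame_interval_s,
                meta={"condition": preset.name, "cell_id": f"{preset.name}_{i:03d}"},
            )
        )
        rows.append(
            {
                "cell_id": f"{preset.name}_{i:03d}",
                "condition": preset.name,
                "D_um2_s": preset.params.D_um2_s,
                "k_on_star_s": preset.params.k_on_star_s,
                "k_off_s": preset.params.k_off_s,
                "bound_fraction": preset.params.bound_fraction,
                "noise_sd": noise_sd,
            }
        )
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microtubule arrays
# ---------------------------------------------------------------------------


@dataclass
class ArrayModel:
    """Worm-like-chain microtubule array in a neurite box.

    Filaments run roughly parallel to the process axis, layered ~70 nm apart
    axially (z).  Lengths are lognormal; the PC12-like scenario is dominated
    by short microtubules (0.5-2.5 um class), the DRG-like scenario by longer
    ones.  Localizations are sampled along each chain at a linear density
    with Gaussian offsets plus uniform clutter.
    """

    box_length_um: float = 12.0
    box_width_um: float = 2.0
    box_depth_um: float = 0.5
    n_filaments: int = 12
    length_log_mean: float = np.log(2.2)  # lognormal parameters, um
    length_log_sd: float = 0.55
    min_length_um: float = 0.5
    persistence_length_um: float = 2000.0  # microtubules are ~mm-stiff
    spacing_nm: float = 70.0  # axial inter-microtubule spacing
    step_nm: float = 26.0  # chain discretization, one render pixel
    axis_angle_sd_rad: float = 0.02  # orientation scatter around the process axis
    min_lateral_separation_nm: float = 0.0  # 0 = unconstrained lateral placement
    loc_density_per_nm: float = 0.15
    sigma_xy_nm: float = 8.0
    sigma_z_nm: float = 12.5  # matches ~25 nm axial resolution
    clutter_per_um3: float = 2.0

    @classmethod
    def pc12(cls) -> "ArrayModel":
        return cls()

    @classmethod
    def drg(cls) -> "ArrayModel":
        return cls(length_log_mean=np.log(5.0), length_log_sd=0.45, box_length_um=15.0)

    @classmethod
    def recovery_benchmark(cls) -> "ArrayModel":
        """Sparse single-layer array with per-filament recoverable ground truth.

        Filaments laterally closer than the line-filter support merge at
        extraction, and tips of distinct collinear filaments within the
        grouping search reach are indistinguishable from a true continuation
        (both are resolution limits of localization-based tracing, not
        algorithm defects).  The per-filament recovery benchmark therefore
        enforces a lateral separation beyond both limits and keeps all
        filaments in one optical section, so the ground truth is
        unambiguously recoverable.
        """
        return cls(
            n_filaments=6,
            box_width_um=5.0,
            box_depth_um=0.15,
            spacing_nm=150.0,
            min_lateral_separation_nm=600.0,
        )


def _wormlike_chain(rng, start_nm, direction, length_nm, step_nm, persistence_nm):
    """2D worm-like chain in the (x, y) plane with the given persistence length."""
    n_steps = max(1, int(round(length_nm / step_nm)))
    angle_sd = np.sqrt(step_nm / persistence_nm)
    theta = np.arctan2(direction[1], direction[0]) + rng.normal(0.0, angle_sd, n_steps).cumsum()
    steps = step_nm * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return start_nm + np.vstack([np.zeros(2), steps.cumsum(axis=0)])


def gen_microtubule_array(
    model: ArrayModel | None = None, seed: int = 0
) -> tuple[pd.DataFrame, list[np.ndarray], LocalizationTable]:
    """Generate a ground-truth filament array and its localization table.

    Returns ``(truth, polylines, locs)``: a per-filament truth table (length,
    straightness, z plane), the ground-truth polylines in nm (x, y columns),
    and the localization table (chain samples with Gaussian offsets plus
    uniform clutter).
    """
    model = model or ArrayModel()
    rng = np.random.default_rng(seed)
    lx = model.box_length_um * 1000.0
    ly = model.box_width_um * 1000.0
    lz = model.box_depth_um * 1000.0
    n_layers = max(1, int(lz // model.spacing_nm))
    polylines = []
    truth_rows = []
    loc_rows = []
    for i in range(model.n_filaments):
        length_nm = 1000.0 * max(
            model.min_length_um, float(rng.lognormal(model.length_log_mean, model.length_log_sd))
        )
        x0 = rng.uniform(0.0, max(lx - length_nm, 1.0))
        y0 = rng.uniform(0.1 * ly, 0.9 * ly)
        if model.min_lateral_separation_nm > 0:
            placed = [r["y0_nm"] for r in truth_rows]
            for _ in range(200):
                if all(abs(y0 - yp) >= model.min_lateral_separation_nm for yp in placed):
                    break
                y0 = rng.uniform(0.1 * ly, 0.9 * ly)
        z = (i % n_layers + 0.5) * model.spacing_nm + rng.normal(0.0, 3.0)
        direction = np.array([1.0, rng.normal(0.0, model.axis_angle_sd_rad)])
        direction /= np.linalg.norm(direction)
        chain = _wormlike_chain(
            rng, np.array([x0, y0]), direction, length_nm, model.step_nm, model.persistence_length_um * 1000.0
        )
        # clip to the box: keep the longest in-box run
        inside = (
            (chain[:, 0] >= 0) & (chain[:, 0] < lx) & (chain[:, 1] >= 0) & (chain[:, 1] < ly)
        )
        if not inside.all():
            runs = np.split(np.arange(len(chain)), np.where(np.diff(inside.astype(int)) != 0)[0] + 1)
            runs = [r for r in runs if inside[r[0]]]
            if not runs:
                continue
            chain = chain[max(runs, key=len)]
        if len(chain) < 2:
            continue
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        contour_um = seg.sum() / 1000.0
        end_to_end_um = np.linalg.norm(chain[-1] - chain[0]) / 1000.0
        polylines.append(chain)
        truth_rows.append(
            {
                "filament_id": len(polylines) - 1,
                "length_um": contour_um,
                "straightness": min(end_to_end_um / contour_um, 1.0),
                "z_nm": z,
                "y0_nm": y0,
            }
        )
        # localizations along the chain
        n_locs = rng.poisson(model.loc_density_per_nm * seg.sum())
        if n_locs == 0:
            continue
        s = np.sort(rng.uniform(0.0, seg.sum(), n_locs))
        cum = np.concatenate([[0.0], seg.cumsum()])
        idx = np.searchsorted(cum, s, side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        frac = (s - cum[idx]) / seg[idx]
        pts = chain[idx] + frac[:, None] * (chain[idx + 1] - chain[idx])
        xy = pts + rng.normal(0.0, model.sigma_xy_nm, (n_locs, 2))
        zs = z + rng.normal(0.0, model.sigma_z_nm, n_locs)
        for (x, y), zv in zip(xy, zs):
            loc_rows.append((x, y, zv))
    # uniform clutter localizations
    n_clutter = rng.poisson(
        model.clutter_per_um3 * model.box_length_um * model.box_width_um * model.box_depth_um
    )
    for _ in range(n_clutter):
        loc_rows.append(
            (rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(0, lz))
        )
    if not loc_rows:
        raise ValueError("generated no localizations; increase density or filament count")
    arr = np.asarray(loc_rows, dtype=float)
    df = pd.DataFrame(
        {
            "frame": rng.integers(0, 10000, len(arr)),
            "x_nm": arr[:, 0],
            "y_nm": arr[:, 1],
            "z_nm": np.clip(arr[:, 2], 0.0, lz - 1e-6),
            "photons": rng.lognormal(7.0, 0.3, len(arr)),
            "precision_xy_nm": np.full(len(arr), model.sigma_xy_nm),
            "precision_z_nm": np.full(len(arr), model.sigma_z_nm),
        }
    )
    truth = pd.DataFrame(
        truth_rows, columns=["filament_id", "length_um", "straightness", "z_nm", "y0_nm"]
    )
    return truth, polylines, LocalizationTable(df)


# ---------------------------------------------------------------------------
# vesicle series
# ---------------------------------------------------------------------------


@dataclass
class MotilityModel:
    """Mixture of directed run-and-pause and stationary jittering vesicles."""

    mobile_fraction: float = 0.6
    speed_range_um_s: tuple[float, float] = (0.5, 1.5)
    pause_probability: float = 0.1  # per frame
    anterograde_fraction: float = 0.7
    jitter_sd_nm: float = 50.0  # stationary positional jitter
    mobile_jitter_sd_nm: float = 20.0
    frame_rate_hz: float = 5.0
    duration_s: float = 60.0
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mobile_fraction", "pause_probability", "anterograde_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def gen_vesicle_series(
    model: MotilityModel | None = None, n_particles: int = 40, seed: int = 0
) -> tuple[DetectionTable, pd.DataFrame]:
    """Simulate a vesicle detection series with per-particle truth labels.

    Mobile particles run along the process axis at a constant speed with
    per-frame pauses; stationary particles jitter around a fixed point.
    Detections are dropped independently at the dropout rate.  The truth
    table records each particle's class, speed, and direction.
    """
    model = model or MotilityModel()
    rng = np.random.default_rng(seed)
    n_frames = int(round(model.duration_s * model.frame_rate_hz))
    dt = 1.0 / model.frame_rate_hz
    rows = []
    truth_rows = []
    for pid in range(n_particles):
        mobile = rng.uniform() < model.mobile_fraction
        x = rng.uniform(5_000.0, 50_000.0)
        y = rng.uniform(1_000.0, 3_000.0)
        speed = float(rng.uniform(*model.speed_range_um_s)) if mobile else 0.0
        direction = 1.0 if rng.uniform() < model.anterograde_fraction else -1.0
        jitter = model.mobile_jitter_sd_nm if mobile else model.jitter_sd_nm
        truth_rows.append(
            {
                "particle_id": pid,
                "mobile": mobile,
                "speed_um_s": speed,
                "direction": int(direction) if mobile else 0,
            }
        )
        for frame in range(n_frames):
            if mobile and rng.uniform() >= model.pause_probability:
                x += direction * speed * 1000.0 * dt
            ox, oy = rng.normal(0.0, jitter, 2)
            if rng.uniform() < model.dropout_rate:
                continue
            rows.append(
                {
                    "frame": frame,
                    "x_nm": x + ox,
                    "y_nm": y + oy,
                    "intensity": float(rng.lognormal(6.0, 0.2)),
                    "particle_id": pid,  # ground-truth column, ignored by linking
                }
            )
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "intensity", "particle_id"])
    return DetectionTable(df, frame_rate_hz=model.frame_rate_hz), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# phosphosite tables
# ---------------------------------------------------------------------------

_MT_GENES = (
    "MAP1A", "MAP1B", "MAP2", "MAPT", "MAP4", "MAP6", "MAP7",
    "STMN1", "STMN2", "STMN3", "STMN4", "MAPRE1", "MAPRE2", "MAPRE3",
    "CLASP1", "CLASP2", "KATNA1", "KATNB1", "FIGN", "SPAST",
    "TUBA1A", "TUBB3", "TUBG1",
)


def _site_frame(keys, condition: str, rng) -> pd.DataFrame:
    rows = [
        {
            "gene": g,
            "residue": r,
            "position": p,
            "log2_fold_change": float(rng.uniform(0.5, 3.0)),
            "p_value": float(rng.uniform(0.0005, 0.04)),
            "condition": condition,
        }
        for g, r, p in keys
    ]
    return pd.DataFrame(
        rows, columns=["gene", "residue", "position", "log2_fold_change", "p_value", "condition"]
    )


def gen_phospho_tables(
    n_background_genes: int = 200,
    sites_per_condition: tuple[int, int] = (40, 82),
    shared_count: int = 4,
    seed: int = 0,
    conditions: tuple[str, str] = ("h2o2", "arsenite"),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two condition site tables sharing exactly ``shared_count`` keys.

    Returns (table_a, table_b, truth) where truth records the shared keys and
    the background gene universe.  Site keys are drawn over a mixed pool of
    microtubule-related and generic background genes.
    """
    n_a, n_b = sites_per_condition
    if shared_count > min(n_a, n_b):
        raise ValueError("shared_count cannot exceed either set size")
    rng = np.random.default_rng(seed)
    genes = list(_MT_GENES) + [f"GENE{i:04d}" for i in range(n_background_genes - len(_MT_GENES))]
    residues = np.array(list("STY"))

    def draw_keys(n, exclude):
        keys = set()
        while len(keys) < n:
            g = genes[int(rng.integers(0, len(genes)))]
            key = (g, str(rng.choice(residues)), int(rng.integers(1, 2500)))
            if key not in exclude and key not in keys:
                keys.add(key)
        return keys

    shared = draw_keys(shared_count, set())
    only_a = draw_keys(n_a - shared_count, shared)
    only_b = draw_keys(n_b - shared_count, shared | only_a)
    keys_a = sorted(shared | only_a)
    keys_b = sorted(shared | only_b)
    table_a = _site_frame(keys_a, conditions[0], rng)
    table_b = _site_frame(keys_b, conditions[1], rng)
    truth = {
        "shared_keys": sorted(shared),
        "background_genes": genes,
        "n_a": n_a,
        "n_b": n_b,
    }
    return table_a, table_b, truth


def phospho_fixture(name: str) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic fixtures mirroring published comparison patterns.

    ``"map1b"``: 22 peroxide-upregulated vs. 27 arsenite-upregulated MAP1B
    sites sharing exactly the key (MAP1B, S, 1772).
    ``"arsenite82"``: 82 arsenite-upregulated sites of which exactly 4 are
    shared with the peroxide set (fraction 4/82 < 5 %).
    """
    rng = np.random.default_rng(20250403)
    if name == "map1b":
        pos_a = [244, 541, 613, 717, 831, 917, 996, 1101, 1208, 1244, 1317,
                 1396, 1432, 1506, 1587, 1622, 1703, 1772, 1825, 1901, 1956, 2041]
        pos_b = [181, 312, 422, 529, 648, 722, 806, 934, 1012, 1122, 1189,
                 1260, 1344, 1402, 1461, 1550, 1618, 1688, 1772, 1836, 1874,
                 1922, 1988, 2012, 2076, 2121, 2204]
        assert len(pos_a) == 22 and len(pos_b) == 27
        keys_a = [("MAP1B", "S", p) for p in pos_a]
        keys_b = [("MAP1B", "S", p) for p in pos_b]
        truth = {"shared_keys": [("MAP1B", "S", 1772)]}
        return _site_frame(keys_a, "h2o2", rng), _site_frame(keys_b, "arsenite", rng), truth
    if name == "arsenite82":
        return gen_phospho_tables(
            n_background_genes=200,
            sites_per_condition=(40, 82),
            shared_count=4,
            seed=8242,
            conditions=("h2o2", "arsenite"),
        )
    raise ValueError(f"unknown fixture {name!r}; available: map1b, arsenite82")
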