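"""Ground-truthed synthetic data: trap pedigrees, movies, and flow plates.

The generator implements a minimal two-step switching model.  At every cell
division a newborn daughter may (rarely) found a *predisposed* clan; within
such a clan, for a heritable span of 1-4 divisions, each division may
trigger *activation* of the Wor1 reporter, which always captures the
dividing mother-daughter pair jointly and is inherited by all descendants.
Reporter kinetics during activation follow a logistic rise from the white
to the opaque level (40-fold higher), with a configurable 10-90% rise time
and a per-event birth-to-max time drawn from a truncated lognormal.

Everything returned is paired with ground truth so downstream stages
(imaging, lineage, eventstats, flowfit) can be tested without real data.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    CONSTRUCT_FREE_GFP, CONSTRUCT_GFP, CONSTRUCT_MGFP, CONSTRUCT_WOR1,
    ConfigError, FlowModelConfig, SwitchModelConfig,
)
from .lineage import CellRecord, Pedigree, Trace, build_pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "PedigreeGroundTruth", "MovieGroundTruth", "FlowPlate",
    "simulate_pedigrees", "simulate_switching_traces", "render_movie",
    "simulate_flow_plate", "simulate_strain_day", "sample_length_dataset",
    "logistic_level", "sample_birth_to_max",
]

_LN19 = math.log(19.0)
_LN81 = math.log(81.0)


# ---------------------------------------------------------------------------
# Reporter kinetics
# ---------------------------------------------------------------------------

def rise_tau_minutes(cfg: SwitchModelConfig) -> float:
    """Logistic time constant (minutes) giving the configured 10-90% rise."""
    return cfg.rise_time_10_90 * 60.0 / _LN81


def logistic_level(t_min: np.ndarray, t0_min: float, tau_min: float,
                   white: float, opaque: float) -> np.ndarray:
    """Reporter level at time t for a logistic white->opaque transition."""
    z = np.clip((np.asarray(t_min, dtype=float) - t0_min) / tau_min, -60, 60)
    return white + (opaque - white) / (1.0 + np.exp(-z))


def sample_birth_to_max(rng: np.random.Generator, cfg: SwitchModelConfig,
                        size: int = 1) -> np.ndarray:
    """Draw birth-to-max times (hours) from a truncated lognormal.

    The lognormal is parameterized so its untruncated arithmetic mean and sd
    equal the configured values; draws are rejected outside the configured
    range (observed span of measured switching events).
    """
    m, s = cfg.birth_to_max_mean, cfg.birth_to_max_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - 0.5 * sigma2
    sigma = math.sqrt(sigma2)
    lo, hi = cfg.birth_to_max_range
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

@dataclass
class PedigreeGroundTruth:
    """Ground truth for a simulated multi-trap experiment.

    ``cells`` has one row per cell (trap_id, cell_id, parent_id,
    birth_frame, end_frame, birth_time_min, class, clan_id, event_frame,
    separation).  ``events`` has one row per activation event (trap_id,
    clan_id, event_time_min, mother_id, daughter_id, separation,
    birth_to_max_h).
    """

    cells: pd.DataFrame
    events: pd.DataFrame
    n_traps: int

    def events_per_trap(self, scheme: int = 3) -> pd.Series:
        """Ground-truth per-trap event counts under a counting scheme.

        Scheme 1 counts every activated mother-daughter pair; scheme 2
        merges pairs connected through uninterrupted chains of switching
        cells; scheme 3 additionally merges all pairs that share an
        ancestor within the trap pedigree.
        """
        if scheme not in (1, 2, 3):
            raise ConfigError(f"unknown counting scheme: {scheme!r}")
        trap_ids = [f"trap{i:03d}" for i in range(self.n_traps)]
        counts = pd.Series(0, index=pd.Index(trap_ids, name="trap_id"))
        for trap_id, ev in self.events.groupby("trap_id"):
            if scheme == 1:
                counts[trap_id] = len(ev)
            elif scheme == 3:
                # all cells in one trap descend from a single founder
                counts[trap_id] = 1 if len(ev) else 0
            else:
                counts[trap_id] = _n_connected_pair_groups(ev)
        return counts

    @property
    def n_zero_event_traps(self) -> int:
        return int((self.events_per_trap(scheme=3) == 0).sum())


def _n_connected_pair_groups(events: pd.DataFrame,
                             sync_window_min: float = 24.0) -> int:
    """Connected components of event pairs (direct-pattern merging).

    Two activation events merge when their cells are mother-daughter
    related *and* the events are synchronous (within the given window):
    simultaneity is what distinguishes a direct pattern from separate
    events within one lineage.
    """
    ev = list(events.itertuples())
    parent = list(range(len(ev)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def related(a: str, b: str) -> bool:
        return (a.rsplit(".", 1)[0] == b if "." in a else False) or \
               (b.rsplit(".", 1)[0] == a if "." in b else False)

    for i in range(len(ev)):
        for j in range(i + 1, len(ev)):
            if abs(ev[i].event_time_min - ev[j].event_time_min) > sync_window_min:
                continue
            cells_i = (ev[i].mother_id, ev[i].daughter_id)
            cells_j = (ev[j].mother_id, ev[j].daughter_id)
            if any(related(a, b) for a in cells_i for b in cells_j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(ev))})


class _SimCell:
    __slots__ = ("name", "birth_time", "div_count", "clan", "dist", "span",
                 "opaque", "switching", "t0", "event_time", "btm", "separation")

    def __init__(self, name: str, birth_time: float):
        self.name = name
        self.birth_time = birth_time
        self.div_count = 0
        self.clan: Optional[int] = None
        self.dist = 0
        self.span = 0
        self.opaque = False        # activated or born with high Wor1
        self.switching = False     # member of an activating pair
        self.t0: Optional[float] = None   # logistic midpoint, minutes
        self.event_time: Optional[float] = None
        self.btm: Optional[float] = None
        self.separation: Optional[int] = None


def _simulate_trap(cfg: SwitchModelConfig, rng: np.random.Generator,
                   trap_id: str, clan_counter: list[int],
                   with_traces: bool) -> tuple[list[CellRecord], list[dict]]:
    movie_end = cfg.movie_minutes
    k = (cfg.division_time_mean / cfg.division_time_sd) ** 2
    theta = cfg.division_time_sd ** 2 / cfg.division_time_mean
    tau = rise_tau_minutes(cfg)
    span_lo, span_hi = cfg.predispose_span

    def next_division(t: float) -> float:
        return t + rng.gamma(k, theta)

    cells: dict[str, _SimCell] = {"0": _SimCell("0", 0.0)}
    heap: list[tuple[float, int, str]] = []
    seq = 0
    heapq.heappush(heap, (next_division(0.0), seq, "0"))
    events: list[dict] = []

    while heap and len(cells) < cfg.trap_capacity:
        t, _, name = heapq.heappop(heap)
        if t > movie_end:
            continue
        mother = cells[name]
        mother.div_count += 1
        dname = f"{name}.{mother.div_count}"
        daughter = _SimCell(dname, t)
        cells[dname] = daughter

        if mother.opaque and (mother.t0 is None or t >= mother.t0):
            # the opaque state is inherited only once Wor1 is already high
            # (past the rise midpoint); daughters budded while a switching
            # mother is still low are born white
            daughter.opaque = True
            daughter.t0 = mother.t0
        elif mother.clan is not None:
            newdist = mother.dist + 1
            if newdist <= mother.span:
                mother.dist = newdist
                daughter.clan, daughter.dist, daughter.span = \
                    mother.clan, newdist, mother.span
                # an already-activated (but still low) mother passes on the
                # predisposition; only non-activated mothers can form a new
                # synchronous pair with the daughter
                if not mother.opaque and rng.random() < cfg.p_activate:
                    btm = float(sample_birth_to_max(rng, cfg, 1)[0])
                    t0 = t + btm * 60.0 - tau * _LN19
                    jitter = rng.uniform(-cfg.frame_interval, cfg.frame_interval)
                    for cell, cell_t0 in ((mother, t0 + jitter), (daughter, t0)):
                        cell.opaque = True
                        cell.switching = True
                        cell.t0 = cell_t0
                        cell.event_time = t
                        cell.btm = btm
                        cell.separation = newdist
                    events.append(dict(
                        trap_id=trap_id, clan_id=mother.clan,
                        event_time_min=t, mother_id=name, daughter_id=dname,
                        separation=newdist, birth_to_max_h=btm))
            else:
                mother.clan = None
        else:
            if rng.random() < cfg.p_predispose:
                clan_counter[0] += 1
                daughter.clan = clan_counter[0]
                daughter.dist = 0
                daughter.span = int(rng.integers(span_lo, span_hi + 1))

        seq += 1
        heapq.heappush(heap, (next_division(t), seq, name))
        seq += 1
        heapq.heappush(heap, (next_division(t), seq, dname))

    # materialize records with traces
    records: list[CellRecord] = []
    sigma = _noise_sigma(cfg.noise_cv)
    last_frame = cfg.n_frames - 1
    for name, cell in cells.items():
        birth_frame = min(int(math.ceil(cell.birth_time / cfg.frame_interval)),
                          last_frame)
        if cell.switching:
            label = "switching"
        elif cell.opaque:
            label = "opaque"
        elif cell.clan is not None:
            label = "predisposed"
        else:
            label = "white"
        trace = None
        if with_traces:
            frames = np.arange(birth_frame, last_frame + 1)
            t_min = frames * cfg.frame_interval
            if cell.opaque and cell.t0 is not None:
                level = logistic_level(t_min, cell.t0, tau,
                                       cfg.white_level, cfg.opaque_level)
            elif cell.opaque:
                level = np.full(len(frames), cfg.opaque_level)
            else:
                level = np.full(len(frames), cfg.white_level)
            if sigma > 0:
                level = level * rng.lognormal(-0.5 * sigma * sigma, sigma,
                                              size=len(frames))
            trace = Trace(frames=frames, values=level)
        records.append(CellRecord(
            cell_id=name, trap_id=trap_id, birth_frame=birth_frame,
            end_frame=last_frame, trace=trace,
            meta=dict(class_label=label, clan_id=cell.clan,
                      birth_time_min=cell.birth_time,
                      event_time_min=cell.event_time, t0_min=cell.t0,
                      birth_to_max_h=cell.btm, separation=cell.separation)))
    return records, events


def simulate_pedigrees(cfg: SwitchModelConfig, seed: Optional[int] = None,
                       with_traces: bool = True,
                       ) -> tuple[list[Pedigree], PedigreeGroundTruth]:
    """Simulate one pedigree per trap under the two-step switching model.

    Returns a list of per-trap pedigrees (cells carry reporter traces when
    ``with_traces``) and the full ground truth.  Identical seeds give
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    pedigrees: list[Pedigree] = []
    all_rows: list[dict] = []
    all_events: list[dict] = []
    clan_counter = [0]
    for i in range(cfg.n_traps):
        trap_id = f"trap{i:03d}"
        records, events = _simulate_trap(cfg, rng, trap_id, clan_counter,
                                         with_traces)
        pedigrees.append(build_pedigree(records, trap_id=trap_id))
        all_events.extend(events)
        for rec in records:
            all_rows.append(dict(
                trap_id=trap_id, cell_id=rec.cell_id,
                parent_id=rec.parent_id or "",
                birth_frame=rec.birth_frame, end_frame=rec.end_frame,
                birth_time_min=rec.meta["birth_time_min"],
                class_label=rec.meta["class_label"],
                clan_id=rec.meta["clan_id"],
                event_frame=(None if rec.meta["event_time_min"] is None else
                             int(round(rec.meta["event_time_min"]
                                       / cfg.frame_interval))),
                separation=rec.meta["separation"]))
    cells_df = pd.DataFrame(all_rows)
    events_df = pd.DataFrame(
        all_events, columns=["trap_id", "clan_id", "event_time_min",
                             "mother_id", "daughter_id", "separation",
                             "birth_to_max_h"])
    gt = PedigreeGroundTruth(cells=cells_df, events=events_df,
                             n_traps=cfg.n_traps)
    logger.info("simulated %d traps: %d cells, %d switching events, "
                "%d zero-event traps", cfg.n_traps, len(cells_df),
                len(events_df), gt.n_zero_event_traps)
    return pedigrees, gt


def simulate_switching_traces(n: int, cfg: SwitchModelConfig,
                              seed: Optional[int] = None,
                              ) -> tuple[list[Trace], pd.DataFrame]:
    """Generate standalone switching-cell traces (born at frame 0).

    Each trace follows the logistic white->opaque rise with a birth-to-max
    time drawn from the configured truncated lognormal, sampled at the
    configured cadence with multiplicative lognormal noise.  Returns the
    traces and a ground-truth table (birth_to_max_h, t0_min, rise_h).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    tau = rise_tau_minutes(cfg)
    sigma = _noise_sigma(cfg.noise_cv)
    frames = np.arange(cfg.n_frames)
    t_min = frames * cfg.frame_interval
    btms = sample_birth_to_max(rng, cfg, n)
    traces, rows = [], []
    for btm in btms:
        t0 = btm * 60.0 - tau * _LN19
        level = logistic_level(t_min, t0, tau, cfg.white_level,
                               cfg.opaque_level)
        if sigma > 0:
            level = level * rng.lognormal(-0.5 * sigma * sigma, sigma,
                                          size=len(frames))
        traces.append(Trace(frames=frames.copy(), values=level))
        rows.append(dict(birth_to_max_h=btm, t0_min=t0,
                         rise_h=cfg.rise_time_10_90))
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

@dataclass
class MovieGroundTruth:
    """Ground truth for a rendered trap movie."""

    offsets: np.ndarray                  # (T, 2) cumulative (dy, dx) drift
    label_map: dict[int, str]            # mask label -> cell_id
    dropped: list[str]                   # cells pushed out of the canvas
    cell_params: pd.DataFrame            # per-cell geometry and levels


_CLASS_AXIS_RATIO = {"white": 1.15, "predisposed": 1.15,
                     "switching": 1.6, "opaque": 1.4}


def _ellipse_mask(a: float, b: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets (rows, cols) of an ellipse centred at the origin."""
    r = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    c, s = math.cos(theta), math.sin(theta)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def render_movie(pedigree: Pedigree, cfg: SwitchModelConfig,
                 canvas_shape: tuple[int, int] = (300, 300),
                 drift: Optional[np.ndarray] = None,
                 noise_sd: float = 0.05,
                 dic_noise_sd: float = 2.0,
                 nucleus_sigma: float = 6.0,
                 top_k: int = 300,
                 spacing: float = 1.0,
                 seed: Optional[int] = None):
    """Render a pedigree as a two-channel trap movie plus label masks.

    Channel 0 is a DIC-like image (background 100, dark interior, bright
    2-px rim); channel 1 is the GFP channel, where each cell has a uniform
    cytoplasm at half its reporter level plus a nuclear Gaussian spot scaled
    so that the mean of the cell's ``top_k`` brightest pixels equals the
    reporter level exactly (before noise).  ``drift`` is a (T, 2) array of
    cumulative integer (dy, dx) offsets applied to both channels and
    recorded in the ground truth.  Cells placed beyond the canvas are
    dropped and logged, emulating cells pushed out of the trap.  ``spacing``
    scales the bud distance (> 1 renders well-separated cells for
    segmentation benchmarks).

    Returns ``(movie, masks, ground_truth)`` where ``movie`` is an
    ``imaging.TrapMovie``, ``masks`` a (T, H, W) uint16 label stack and
    ``ground_truth`` a :class:`MovieGroundTruth`.
    """
    from .imaging import TrapMovie

    rng = np.random.default_rng(seed)
    T = cfg.n_frames
    H, W = canvas_shape
    if drift is None:
        offsets = np.zeros((T, 2), dtype=int)
    else:
        offsets = np.asarray(drift, dtype=int)
        if offsets.shape != (T, 2):
            raise ConfigError(f"drift must have shape ({T}, 2)")
    tau = rise_tau_minutes(cfg)

    # --- static placement: founder at centre, daughters budded outward ---
    order = sorted(pedigree.names(),
                   key=lambda n: (pedigree.records[n].birth_frame, n))
    positions: dict[str, tuple[float, float]] = {}
    geometry: dict[str, dict] = {}
    dropped: list[str] = []
    margin = 4
    for name in order:
        rec = pedigree.records[name]
        label = rec.meta.get("class_label", "white")
        area = cfg.opaque_area if label in ("opaque", "switching") else cfg.white_area
        q = _CLASS_AXIS_RATIO.get(label, 1.15)
        a = math.sqrt(area * q / math.pi)
        b = math.sqrt(area / (math.pi * q))
        theta = rng.uniform(0, math.pi)
        radius = math.sqrt(area / math.pi)
        parent = rec.parent_id
        if parent is None or parent not in positions:
            pos = (H / 2.0, W / 2.0) if parent is None else None
            if pos is None:
                dropped.append(name)
                continue
        else:
            py, px = positions[parent]
            pr = math.sqrt(geometry[parent]["area"] / math.pi)
            best, best_pen = None, np.inf
            for _ in range(12):
                ang = rng.uniform(0, 2 * math.pi)
                dist = (pr + radius + 1.0) * spacing
                cy = py + dist * math.sin(ang)
                cx = px + dist * math.cos(ang)
                pen = 0.0
                for oy, ox in positions.values():
                    d = math.hypot(cy - oy, cx - ox)
                    pen += max(0.0, 2 * radius * spacing - d)
                if pen < best_pen:
                    best, best_pen = (cy, cx), pen
                if pen == 0.0:
                    break
            pos = best
        cy, cx = pos
        rmax = max(a, b)
        if not (margin + rmax <= cy <= H - margin - rmax
                and margin + rmax <= cx <= W - margin - rmax):
            dropped.append(name)
            logger.warning("cell %s pushed out of the trap canvas", name)
            continue
        positions[name] = (cy, cx)
        geometry[name] = dict(area=area, a=a, b=b, theta=theta)

    # --- precompute per-cell pixel offsets and nuclear weighting ---
    cell_pixels: dict[str, dict] = {}
    for name, (cy, cx) in positions.items():
        g = geometry[name]
        ry, rx = _ellipse_mask(g["a"], g["b"], g["theta"])
        d2 = ry.astype(float) ** 2 + rx.astype(float) ** 2
        gauss = np.exp(-d2 / (2.0 * nucleus_sigma ** 2))
        kk = min(top_k, len(gauss))
        top_gauss = np.partition(gauss, len(gauss) - kk)[len(gauss) - kk:]
        cell_pixels[name] = dict(ry=ry, rx=rx, gauss=gauss,
                                 mean_top_gauss=float(np.mean(top_gauss)),
                                 cy=cy, cx=cx)

    dic = np.full((T, H, W), 100.0, dtype=np.float32)
    gfp = np.zeros((T, H, W), dtype=np.float32)
    masks = np.zeros((T, H, W), dtype=np.uint16)
    label_map: dict[int, str] = {}
    name_to_label = {}
    for i, name in enumerate(sorted(positions), start=1):
        label_map[i] = name
        name_to_label[name] = i

    params_rows = []
    for f in range(T):
        t_now = f * cfg.frame_interval
        dy, dx = offsets[f]
        for name, px in cell_pixels.items():
            rec = pedigree.records[name]
            if not (rec.birth_frame <= f <= rec.end_frame):
                continue
            meta = rec.meta
            t0 = meta.get("t0_min")
            if meta.get("class_label") in ("opaque", "switching"):
                level = (cfg.opaque_level if t0 is None else float(
                    logistic_level(np.array([t_now]), t0, tau,
                                   cfg.white_level, cfg.opaque_level)[0]))
            else:
                level = cfg.white_level
            rows = np.round(px["cy"] + dy).astype(int) + px["ry"]
            cols = np.round(px["cx"] + dx).astype(int) + px["rx"]
            ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
            rows, cols = rows[ok], cols[ok]
            gvals = px["gauss"][ok]
            # DIC: dark interior with a bright rim (2 px)
            g = geometry[name]
            u = ((cols - round(px["cx"] + dx)) * math.cos(g["theta"])
                 + (rows - round(px["cy"] + dy)) * math.sin(g["theta"]))
            v = (-(cols - round(px["cx"] + dx)) * math.sin(g["theta"])
                 + (rows - round(px["cy"] + dy)) * math.cos(g["theta"]))
            rr = (u / g["a"]) ** 2 + (v / g["b"]) ** 2
            rim = rr > (1.0 - 2.0 / max(g["b"], 2.0)) ** 2
            dic[f, rows, cols] = np.where(rim, 160.0, 85.0)
            # GFP: cytoplasm at level/2 plus nuclear spot hitting the
            # top-k metric exactly
            amp = 0.5 * level / px["mean_top_gauss"]
            gfp[f, rows, cols] = 0.5 * level + amp * gvals
            masks[f, rows, cols] = name_to_label[name]

    for name in sorted(positions):
        g = geometry[name]
        px = cell_pixels[name]
        params_rows.append(dict(
            cell_id=name, label=name_to_label[name], row=px["cy"],
            col=px["cx"], area=g["area"], major_axis=2 * g["a"],
            minor_axis=2 * g["b"], theta=g["theta"]))

    if dic_noise_sd > 0:
        dic += rng.normal(0.0, dic_noise_sd, size=dic.shape).astype(np.float32)
    if noise_sd > 0:
        gfp += rng.normal(0.0, noise_sd, size=gfp.shape).astype(np.float32)

    frames = np.stack([dic, gfp], axis=1)
    movie = TrapMovie(frames=frames, frame_interval=cfg.frame_interval,
                      trap_id=pedigree.trap_id)
    gt = MovieGroundTruth(offsets=offsets, label_map=label_map,
                          dropped=dropped,
                          cell_params=pd.DataFrame(params_rows))
    return movie, masks, gt


# ---------------------------------------------------------------------------
# Morphometry dataset
# ---------------------------------------------------------------------------

def sample_length_dataset(cfg: SwitchModelConfig, n_pairs: int = 248,
                          n_white: int = 100, n_opaque: int = 100,
                          seed: Optional[int] = None) -> dict[str, np.ndarray]:
    """Sample cell lengths (pixels) for switching pairs plus references.

    Lengths are lognormal per class with the configured ``length_dists``;
    switching daughters are frequently pseudohyphal (elongated) while
    switching mothers mostly resemble white cells.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    d = cfg.length_dists
    out = {}
    for key, n, cls in (("mothers", n_pairs, "switching-mother"),
                        ("daughters", n_pairs, "switching-daughter"),
                        ("white_ref", n_white, "white"),
                        ("opaque_ref", n_opaque, "opaque")):
        mu, sd = d[cls]
        out[key] = rng.lognormal(mu, sd, size=n)
    return out


# ---------------------------------------------------------------------------
# Flow-cytometry plates
# ---------------------------------------------------------------------------

@dataclass
class FlowPlate:
    """Per-event flow channels for one plate (or one strain-day subset).

    ``events`` columns: well, strain, construct, day, hormone_nM, FSC, SSC,
    GFP, mCherry, V670 plus ground-truth columns true_label, true_protein,
    true_reporter.
    """

    events: pd.DataFrame
    config: FlowModelConfig = field(default_factory=FlowModelConfig)

    def __len__(self) -> int:
        return len(self.events)


def protein_induction(hormone_nM: np.ndarray, cfg: FlowModelConfig,
                      construct: str = CONSTRUCT_MGFP) -> np.ndarray:
    """Median induced protein level per well (saturating Hill in hormone)."""
    h = np.asarray(hormone_nM, dtype=float)
    f = np.where(h > 0,
                 h ** cfg.protein_hill /
                 (h ** cfg.protein_hill + cfg.protein_halfmax_nM ** cfg.protein_hill),
                 0.0)
    level = cfg.protein_basal + (cfg.protein_max - cfg.protein_basal) * f
    if construct == CONSTRUCT_FREE_GFP:
        level = level * cfg.free_gfp_scale
    return level


def reporter_response_log10(protein: np.ndarray, cfg: FlowModelConfig,
                            construct: str) -> np.ndarray:
    """True reporter output (log10 units) as a Hill function of protein."""
    p = np.asarray(protein, dtype=float)
    c, d = cfg.reporter_log10_basal, cfg.reporter_log10_max
    if construct == CONSTRUCT_FREE_GFP:
        return np.full(p.shape, c)
    if construct == CONSTRUCT_GFP:
        hill, K = cfg.hill_gfp, cfg.halfmax_gfp
    else:  # Wor1-mGFP and unlabeled Wor1 behave as monomer-like activators
        hill, K = cfg.hill_mgfp, cfg.halfmax_mgfp
    f = p ** hill / (p ** hill + K ** hill)
    return c + (d - c) * f


def _simulate_well(cfg: FlowModelConfig, rng: np.random.Generator,
                   construct: str, hormone: float) -> pd.DataFrame:
    n = cfg.events_per_well
    n_debris = rng.binomial(n, cfg.debris_frac)
    n_agg = rng.binomial(n - n_debris,
                         cfg.aggregate_frac / (1.0 - cfg.debris_frac))
    n_intact = n - n_debris - n_agg

    sig = _noise_sigma
    med_protein = float(protein_induction(np.array([hormone]), cfg,
                                          construct)[0])

    # intact cells
    protein = med_protein * rng.lognormal(0.0, sig(cfg.protein_cv), n_intact)
    rep_log10 = reporter_response_log10(protein, cfg, construct)
    if construct == CONSTRUCT_GFP and hormone >= cfg.gfp_decline_threshold:
        rep_log10 = rep_log10 - cfg.decline_log10_per_decade * math.log10(
            hormone / cfg.gfp_decline_threshold)
    reporter = 10.0 ** rep_log10
    fsc = rng.lognormal(math.log(cfg.fsc_median), sig(cfg.fsc_cv), n_intact)
    ssc = rng.lognormal(math.log(cfg.ssc_median), sig(cfg.ssc_cv), n_intact)
    scale = fsc / cfg.fsc_median
    if construct == CONSTRUCT_WOR1:
        gfp_signal = rng.lognormal(math.log(5.0), 0.3, n_intact)  # autofluor
    else:
        gfp_signal = protein * rng.lognormal(0.0, sig(cfg.meas_cv_gfp), n_intact)
    gfp = gfp_signal * scale
    mch = reporter * scale * rng.lognormal(0.0, sig(cfg.meas_cv_mcherry), n_intact)
    v670 = rng.lognormal(math.log(cfg.v670_median), sig(cfg.v670_cv), n_intact)
    intact = pd.DataFrame(dict(
        FSC=fsc, SSC=ssc, GFP=gfp, mCherry=mch, V670=v670,
        true_label="intact", true_protein=protein, true_reporter=reporter))

    # debris: small scatter, dim everywhere
    debris = pd.DataFrame(dict(
        FSC=rng.lognormal(math.log(800.0), 0.4, n_debris),
        SSC=rng.lognormal(math.log(600.0), 0.5, n_debris),
        GFP=rng.lognormal(math.log(30.0), 0.6, n_debris),
        mCherry=rng.lognormal(math.log(30.0), 0.6, n_debris),
        V670=rng.lognormal(math.log(300.0), 0.5, n_debris),
        true_label="debris", true_protein=np.nan, true_reporter=np.nan))

    # aggregates: large scatter, high violet autofluorescence
    agg_protein = med_protein * rng.lognormal(0.0, 0.5, n_agg) * 2.0
    agg = pd.DataFrame(dict(
        FSC=rng.lognormal(math.log(5.0e4), 0.3, n_agg),
        SSC=rng.lognormal(math.log(5.0e4), 0.3, n_agg),
        GFP=agg_protein * rng.lognormal(0.0, 0.3, n_agg) * 5.0,
        mCherry=(10.0 ** reporter_response_log10(agg_protein, cfg, construct)
                 * rng.lognormal(0.0, 0.5, n_agg) * 5.0),
        V670=rng.lognormal(math.log(2500.0), 0.4, n_agg),
        true_label="aggregate", true_protein=np.nan, true_reporter=np.nan))

    df = pd.concat([intact, debris, agg], ignore_index=True)
    return df


DEFAULT_STRAINS = (
    ("mGFP-a", CONSTRUCT_MGFP), ("mGFP-alpha", CONSTRUCT_MGFP),
    ("GFP-a", CONSTRUCT_GFP), ("GFP-alpha", CONSTRUCT_GFP),
    ("freeGFP-a", CONSTRUCT_FREE_GFP), ("freeGFP-alpha", CONSTRUCT_FREE_GFP),
    ("Wor1-a", CONSTRUCT_WOR1), ("Wor1-alpha", CONSTRUCT_WOR1),
)


def simulate_flow_plate(cfg: FlowModelConfig,
                        strains: Sequence[tuple[str, str]] = DEFAULT_STRAINS,
                        day: int = 1,
                        seed: Optional[int] = None) -> FlowPlate:
    """Simulate one flow plate: each strain measured at every hormone level.

    Every event carries a ground-truth subpopulation label (intact, debris,
    aggregate) and, for intact events, its true protein and reporter values.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    frames = []
    for strain, construct in strains:
        for j, hormone in enumerate(cfg.hormone_concs):
            df = _simulate_well(cfg, rng, construct, float(hormone))
            df.insert(0, "well", f"{strain}-c{j:02d}")
            df.insert(1, "strain", strain)
            df.insert(2, "construct", construct)
            df.insert(3, "day", day)
            df.insert(4, "hormone_nM", float(hormone))
            frames.append(df)
    return FlowPlate(events=pd.concat(frames, ignore_index=True), config=cfg)


def simulate_strain_day(construct: str, cfg: FlowModelConfig,
                        strain: Optional[str] = None, day: int = 1,
                        seed: Optional[int] = None) -> FlowPlate:
    """Simulate the ten wells of a single strain on a single day."""
    strain = strain or construct
    return simulate_flow_plate(cfg, strains=((strain, construct),),
                               day=day, seed=seed)
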