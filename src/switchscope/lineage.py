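"""Pedigree data model, trace smoothing, and switching-event classification.

Cell identities use dotted pedigree names: the parent of ``"2.1"`` is
``"2"``, which in turn is the second daughter of ``"0"``.  Root cells carry
single-token names.  Daughter numbering is in birth order, so the integer
suffixes along a path count the cell divisions separating two relatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import ConfigError, DataError

__all__ = [
    "Trace", "CellRecord", "Pedigree", "SwitchCall", "SwitchGroup",
    "parent_name", "build_pedigree", "smooth_trace", "classify_switch",
    "group_switching_cells", "divisions_between",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Per-cell time series of the top-k fluorescence metric."""

    frames: np.ndarray                 # int frame indices, strictly increasing
    values: np.ndarray                 # metric per frame
    smoothed: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise DataError("trace frames and values must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise DataError("trace frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def hours_from_birth(self, frame_interval: float) -> np.ndarray:
        """Time of each sample in hours since the first recorded frame."""
        return (self.frames - self.frames[0]) * frame_interval / 60.0


@dataclass
class CellRecord:
    cell_id: str
    trap_id: str = "trap0"
    birth_frame: int = 0
    end_frame: int = 0
    trace: Optional[Trace] = None
    nucleus_lost_frame: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end_frame < self.birth_frame:
            raise DataError(
                f"cell {self.cell_id}: end_frame {self.end_frame} precedes "
                f"birth_frame {self.birth_frame}")

    @property
    def parent_id(self) -> Optional[str]:
        return parent_name(self.cell_id)


def parent_name(cell_id: str) -> Optional[str]:
    """Parent implied by a dotted pedigree name; None for roots."""
    if "." not in cell_id:
        return None
    return cell_id.rsplit(".", 1)[0]


def _check_name(cell_id: str) -> None:
    tokens = cell_id.split(".")
    if not tokens or any(not t.isdigit() for t in tokens):
        raise DataError(f"invalid pedigree name: {cell_id!r}")


class Pedigree:
    """A forest of cells linked by their dotted names (typically one trap)."""

    def __init__(self, records: dict[str, CellRecord], trap_id: str = "trap0"):
        self.records = records
        self.trap_id = trap_id
        self.children: dict[str, list[str]] = {name: [] for name in records}
        self.roots: list[str] = []
        for name in records:
            p = parent_name(name)
            if p is None:
                self.roots.append(name)
            else:
                self.children[p].append(name)
        # daughter order = numeric suffix order
        for kids in self.children.values():
            kids.sort(key=lambda n: int(n.rsplit(".", 1)[1]))
        self.roots.sort(key=int)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def names(self) -> list[str]:
        return list(self.records)

    def parent_of(self, name: str) -> Optional[str]:
        return parent_name(name)

    def children_of(self, name: str) -> list[str]:
        return self.children[name]

    def ancestors(self, name: str) -> list[str]:
        out = []
        p = parent_name(name)
        while p is not None:
            out.append(p)
            p = parent_name(p)
        return out

    def mrca(self, a: str, b: str) -> Optional[str]:
        """Most recent common ancestor-or-self of two cells (None if disjoint)."""
        ta, tb = a.split("."), b.split(".")
        k = 0
        while k < min(len(ta), len(tb)) and ta[k] == tb[k]:
            k += 1
        if k == 0:
            return None
        return ".".join(ta[:k])


def divisions_between(ancestor: str, descendant: str) -> int:
    """Number of cell divisions separating a descendant from an ancestor.

    Counts divisions along the pedigree path: each dotted suffix is the
    birth-order index of a daughter, i.e. the number of divisions its mother
    had undergone when it was born.  The ancestor itself gives 0.
    """
    if descendant == ancestor:
        return 0
    if not descendant.startswith(ancestor + "."):
        raise DataError(f"{descendant!r} is not a descendant of {ancestor!r}")
    suffix = descendant[len(ancestor) + 1:]
    return sum(int(tok) for tok in suffix.split("."))


def build_pedigree(records: list[CellRecord], trap_id: Optional[str] = None) -> Pedigree:
    """Assemble a pedigree forest from cell records with dotted names.

    Raises DataError listing every orphan (a non-root cell whose implied
    parent is absent) or duplicate name.
    """
    table: dict[str, CellRecord] = {}
    for rec in records:
        _check_name(rec.cell_id)
        if rec.cell_id in table:
            raise DataError(f"duplicate cell name: {rec.cell_id!r}")
        table[rec.cell_id] = rec
    orphans = [name for name in table
               if parent_name(name) is not None and parent_name(name) not in table]
    if orphans:
        raise DataError(
            "orphan cells (parent missing): " + ", ".join(sorted(orphans)))
    for rec in table.values():
        p = parent_name(rec.cell_id)
        if p is not None and rec.birth_frame < table[p].birth_frame:
            raise DataError(
                f"cell {rec.cell_id} born before its mother {p}")
    if trap_id is None:
        trap_id = records[0].trap_id if records else "trap0"
    return Pedigree(table, trap_id=trap_id)


# ---------------------------------------------------------------------------
# Trace smoothing
# ---------------------------------------------------------------------------

def smooth_trace(trace: Trace, span: float = 0.3) -> Trace:
    """LOESS-smooth a trace (locally weighted linear regression).

    ``span`` is the fraction of points in each local window; endpoints are
    handled by the one-sided windows inherent to local regression.
    """
    if not (0.0 < span <= 1.0):
        raise ConfigError(f"span must be in (0, 1], got {span!r}")
    if len(trace) < 5:
        raise DataError("smoothing requires at least 5 trace points")
    sm = lowess(trace.values, trace.frames.astype(float),
                frac=span, it=0, return_sorted=False)
    return Trace(frames=trace.frames.copy(), values=trace.values.copy(),
                 smoothed=np.asarray(sm, dtype=float))


def _smooth_for_calling(trace: Trace, window_frames: int) -> np.ndarray:
    """Smooth with a fixed-width window so kinetics are cadence-independent.

    A relative LOESS span on long traces would average over many hours and
    distort a ~3 h rise, so switch calling uses a window of a fixed number
    of frames instead.
    """
    n = len(trace)
    if n < 5:
        return trace.values.astype(float)
    frac = min(1.0, max(window_frames, 3) / n)
    return np.asarray(
        lowess(trace.values, trace.frames.astype(float),
               frac=frac, it=0, return_sorted=False), dtype=float)


# ---------------------------------------------------------------------------
# Switch classification
# ---------------------------------------------------------------------------

@dataclass
class SwitchCall:
    """Classification of one cell's trace against white/opaque references."""

    state: str                          # "white" | "switching" | "opaque"
    t_activation_start: float = math.nan  # hours from birth (10% crossing)
    t_max: float = math.nan             # hours from birth (95% of own max)
    rise_10_90: float = math.nan        # hours
    threshold: float = math.nan         # geometric-mean level used
    low_confidence: bool = False


def _first_upcross(t: np.ndarray, y: np.ndarray, level: float,
                   start_idx: int = 0) -> float:
    """Linearly interpolated first upward crossing time of ``level``."""
    for i in range(max(start_idx, 1), len(y)):
        if y[i - 1] < level <= y[i]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            return t[i - 1] + f * (t[i] - t[i - 1])
    if len(y) and y[0] >= level:
        return t[0]
    return math.nan


def classify_switch(trace: Trace, white_level: float, opaque_level: float,
                    frame_interval: float = 12.0,
                    persistence_frames: int = 3,
                    smooth_window_frames: int = 7,
                    nucleus_lost_frame: Optional[int] = None) -> SwitchCall:
    """Call a cell white / switching / opaque from its fluorescence trace.

    A cell is called opaque-state (either "switching", if it started low, or
    "opaque", if born high) when its smoothed trace exceeds the geometric
    mean of the white and opaque reference levels for at least
    ``persistence_frames`` consecutive frames.  ``t_max`` is the first time
    the smoothed trace reaches 95% of its own maximum; the 10-90% rise time
    is measured against the white-to-opaque reference range.  Times are in
    hours from the cell's first recorded frame.

    Frames at or after ``nucleus_lost_frame`` are excluded (the top-pixel
    metric is meaningless once the nucleus has migrated to the daughter).
    """
    if opaque_level <= white_level:
        raise ConfigError("opaque_level must exceed white_level")
    frames, values = trace.frames, trace.values
    if nucleus_lost_frame is not None:
        keep = frames < nucleus_lost_frame
        frames, values = frames[keep], values[keep]
    thr = math.sqrt(white_level * opaque_level)
    if len(frames) < max(persistence_frames, 5):
        return SwitchCall(state="white", threshold=thr, low_confidence=True)

    sub = Trace(frames=frames, values=values)
    sm = (trace.smoothed if trace.smoothed is not None
          and nucleus_lost_frame is None
          else _smooth_for_calling(sub, smooth_window_frames))
    t = (frames - frames[0]) * frame_interval / 60.0

    above = sm > thr
    run, opaque = 0, False
    for a in above:
        run = run + 1 if a else 0
        if run >= persistence_frames:
            opaque = True
            break
    if not opaque:
        return SwitchCall(state="white", threshold=thr)

    state = "opaque" if sm[0] > thr else "switching"
    rng = opaque_level - white_level
    t10 = _first_upcross(t, sm, white_level + 0.10 * rng)
    t90 = _first_upcross(t, sm, white_level + 0.90 * rng)
    # the cell's own maximum, estimated robustly from the plateau (median of
    # the top decile) so residual noise peaks do not delay the 95% crossing
    n_top = max(3, len(sm) // 10)
    own_max = float(np.median(np.sort(sm)[-n_top:]))
    t_max = _first_upcross(t, sm, 0.95 * own_max)
    rise = t90 - t10 if math.isfinite(t10) and math.isfinite(t90) else math.nan
    return SwitchCall(state=state, t_activation_start=t10, t_max=t_max,
                      rise_10_90=rise, threshold=thr)


# ---------------------------------------------------------------------------
# Switching groups
# ---------------------------------------------------------------------------

@dataclass
class SwitchGroup:
    """A maximal connected set of switching cells within one pedigree."""

    cells: list[str]
    pairs: list[tuple[str, str]]        # synchronous mother-daughter pairs
    label: str = "direct-pair"          # direct-pair | four-cell | mixed-fate-member
    mrca: Optional[str] = None          # MRCA of switching cells in the pedigree
    separation: Optional[int] = None    # divisions from establishing ancestor
    trap_id: str = "trap0"


def group_switching_cells(pedigree: Pedigree, calls: dict[str, SwitchCall],
                          frame_interval: float = 12.0,
                          synchrony_frames: int = 2) -> list[SwitchGroup]:
    """Group switching cells into connected pedigree components.

    Cells whose state is "switching" (activated during the movie) are
    connected through mother-daughter edges *when their activations are
    synchronous* (starting within ``synchrony_frames`` frames of each
    other): simultaneous activation is what distinguishes a direct pattern
    (pair or four-cell chain) from separate events in one lineage.  The
    synchronous mother-daughter pairs within each group are the unit
    counted by scheme 1.  If the pedigree holds more than one group, all
    its groups are mixed-fate members and their separation (in divisions)
    from the establishing ancestor — the MRCA of all switching cells — is
    recorded.
    """
    missing = [n for n in pedigree.names() if n not in calls]
    if missing:
        raise DataError("calls missing for cells: " + ", ".join(sorted(missing)[:5]))
    switching = [n for n in pedigree.names() if calls[n].state == "switching"]
    if not switching:
        return []
    sw = set(switching)

    def _abs_start_frame(n: str) -> float:
        rec = pedigree.records[n]
        t10 = calls[n].t_activation_start
        if not math.isfinite(t10):
            return math.nan
        return rec.birth_frame + t10 * 60.0 / frame_interval

    def _synchronous(a: str, b: str) -> bool:
        dt = abs(_abs_start_frame(a) - _abs_start_frame(b))
        return math.isfinite(dt) and dt <= synchrony_frames + 1e-9

    # connected components over synchronous mother-daughter edges
    comp: dict[str, int] = {}
    groups: list[list[str]] = []
    for name in switching:
        if name in comp:
            continue
        stack, members = [name], []
        comp[name] = len(groups)
        while stack:
            cur = stack.pop()
            members.append(cur)
            nbrs = [p for p in [parent_name(cur)] if p in sw]
            nbrs += [c for c in pedigree.children_of(cur) if c in sw]
            for nb in nbrs:
                if nb not in comp and _synchronous(cur, nb):
                    comp[nb] = len(groups)
                    stack.append(nb)
        groups.append(sorted(members))

    out: list[SwitchGroup] = []
    mixed = len(groups) > 1
    establishing = None
    if mixed:
        establishing = switching[0]
        for n in switching[1:]:
            m = pedigree.mrca(establishing, n)
            if m is None:
                establishing = None
                break
            establishing = m

    for members in groups:
        pairs = []
        for n in members:
            p = parent_name(n)
            if p in sw and p in members:
                dt = abs(_abs_start_frame(n) - _abs_start_frame(p))
                if math.isfinite(dt) and dt <= synchrony_frames + 1e-9:
                    pairs.append((p, n))
        if mixed:
            label = "mixed-fate-member"
        elif len(members) <= 2:
            label = "direct-pair"
        else:
            label = "four-cell"
        sep = None
        if mixed and establishing is not None:
            # anchor on the newborn daughter of each synchronous pair: the
            # activating division is the daughter's birth
            anchors = [c for (_, c) in pairs
                       if c.startswith(establishing + ".")] or \
                      [n for n in members
                       if n == establishing or n.startswith(establishing + ".")]
            if anchors:
                sep = min(divisions_between(establishing, n) for n in anchors)
        out.append(SwitchGroup(cells=members, pairs=pairs, label=label,
                               mrca=establishing if mixed else
                               (pedigree.mrca(members[0], members[-1])),
                               separation=sep, trap_id=pedigree.trap_id))
    return out
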