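"""Spine identity tracking across sessions and turnover statistics.

Between consecutive sessions spines are matched by position: a spine whose
position shifted by >= 500 nm relative to its neighbours is scored as a
different (new) spine. Matching is greedy nearest-neighbour under that
gate, mirroring a human scrolling chronologically through the stacks.

From the matched series three headline fractions follow:

    F_s(t)    = N_r(t) / N(1) * 100      survival fraction: spines present
                                         at the first session and
                                         continuously visible through t
    F_lost(t) = N_L(t) / N(t-1) * 100    fraction of the previous session's
                                         spines that disappeared by t
    F_new(t)  = N_n(t) / N(t) * 100      fraction of the current session's
                                         spines that are new since t-1

A spine that disappears and later reappears within the gate counts as a
new spine; survival requires continuous presence. The dendrite is the unit
of analysis: per-dendrite fractions are aggregated as mean +/- sem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GATE_UM = 0.5


def _positions(obj):
    """Extract [(id, x_um), ...] plus a dendrite tag from supported inputs."""
    if hasattr(obj, "positions") and hasattr(obj, "dendrite_id"):
        return obj.positions(), obj.dendrite_id
    return [(str(i), float(x)) for i, x in obj], None


@dataclass
class Matching:
    """Outcome of matching one pair of consecutive sessions."""

    pairs: list            # (prev_id, curr_id, distance_um)
    lost: list             # prev ids with no partner
    new: list              # curr ids with no partner

    @property
    def prev_to_curr(self) -> dict:
        return {p: c for p, c, _ in self.pairs}


def match_spines(prev, curr, gate: float = DEFAULT_GATE_UM) -> Matching:
    """Greedy nearest-neighbour matching of spine positions under a gate.

    ``prev`` and ``curr`` are sequences of (id, x_um) pairs or observed
    scenes. Candidate pairs closer than ``gate`` are accepted in order of
    ascending distance (ties: smaller previous then current position), each
    spine at most once. Unmatched previous spines are lost; unmatched
    current spines are new.
    """
    prev_list, prev_tag = _positions(prev)
    curr_list, curr_tag = _positions(curr)
    if prev_tag is not None and curr_tag is not None and prev_tag != curr_tag:
        raise ValueError(
            f"cannot match across dendrites ({prev_tag!r} vs {curr_tag!r})"
        )
    candidates = sorted(
        (
            (abs(xp - xc), xp, xc, ip, ic)
            for ip, xp in prev_list
            for ic, xc in curr_list
            if abs(xp - xc) < gate
        ),
    )
    used_prev: set = set()
    used_curr: set = set()
    pairs = []
    for d, xp, xc, ip, ic in candidates:
        if ip in used_prev or ic in used_curr:
            continue
        used_prev.add(ip)
        used_curr.add(ic)
        pairs.append((ip, ic, d))
    lost = [ip for ip, _ in prev_list if ip not in used_prev]
    new = [ic for ic, _ in curr_list if ic not in used_curr]
    return Matching(pairs=pairs, lost=lost, new=new)


@dataclass
class SessionCounts:
    """Per-session bookkeeping of one dendrite's matched series.

    Arrays are indexed by session (0-based); the interval quantities
    N_L and N_n are zero at session 0.
    """

    N: np.ndarray
    N_r: np.ndarray
    N_L: np.ndarray
    N_n: np.ndarray
    dendrite_id: str = "d0"

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=int)
        self.N_r = np.asarray(self.N_r, dtype=int)
        self.N_L = np.asarray(self.N_L, dtype=int)
        self.N_n = np.asarray(self.N_n, dtype=int)
        if not (len(self.N) == len(self.N_r) == len(self.N_L) == len(self.N_n)):
            raise ValueError("count arrays must share a length")
        if self.N_r[0] != self.N[0]:
            raise ValueError("N_r at the first session must equal N(1)")
        if np.any(np.diff(self.N_r) > 0):
            raise ValueError("N_r must be non-increasing")

    @property
    def n_sessions(self) -> int:
        return len(self.N)

    def check_conservation(self) -> bool:
        """N(t) = N(t-1) - N_L(t) + N_n(t) on every interval."""
        return bool(
            np.all(self.N[1:] == self.N[:-1] - self.N_L[1:] + self.N_n[1:])
        )


def track_sessions(sessions, gate: float = DEFAULT_GATE_UM,
                   use_ids: bool = False, dendrite_id: str = "d0"):
    """Match a whole series and tally counts.

    ``sessions`` is a list (one per session) of (id, x_um) sequences or
    observed scenes. With ``use_ids=True`` the position matcher is bypassed
    and ground-truth identities are intersected directly.

    Returns (SessionCounts, list of Matching per interval).
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    pos_lists = []
    for s in sessions:
        plist, tag = _positions(s)
        if tag is not None:
            dendrite_id = tag
        pos_lists.append(plist)

    n_sessions = len(pos_lists)
    N = [len(p) for p in pos_lists]
    N_L = [0]
    N_n = [0]
    N_r = [N[0]]
    matchings = []
    # ids (session-local) of spines continuously present since session 0
    alive_since_start = {i for i, _ in pos_lists[0]}
    for t in range(1, n_sessions):
        if use_ids:
            prev_ids = {i for i, _ in pos_lists[t - 1]}
            curr_ids = {i for i, _ in pos_lists[t]}
            common = prev_ids & curr_ids
            m = Matching(
                pairs=[(i, i, 0.0) for i in sorted(common)],
                lost=sorted(prev_ids - curr_ids),
                new=sorted(curr_ids - prev_ids),
            )
            alive_since_start &= curr_ids
        else:
            m = match_spines(pos_lists[t - 1], pos_lists[t], gate)
            fwd = m.prev_to_curr
            alive_since_start = {
                fwd[i] for i in alive_since_start if i in fwd
            }
        matchings.append(m)
        N_L.append(len(m.lost))
        N_n.append(len(m.new))
        N_r.append(len(alive_since_start))
    counts = SessionCounts(N, N_r, N_L, N_n, dendrite_id=dendrite_id)
    return counts, matchings


def survival_fraction(counts: SessionCounts) -> np.ndarray:
    """F_s(t) = N_r(t)/N(1) * 100 for every session (100 at the first)."""
    if counts.N[0] == 0:
        raise ValueError("survival fraction undefined: no spines at session 1")
    return counts.N_r / counts.N[0] * 100.0


def lost_fraction(counts: SessionCounts) -> np.ndarray:
    """F_lost(t) = N_L(t)/N(t-1) * 100 per interval (indexed by session t >= 1)."""
    prev = counts.N[:-1]
    if np.any(prev == 0):
        raise ValueError("lost fraction undefined: empty earlier session")
    return counts.N_L[1:] / prev * 100.0


def new_fraction(counts: SessionCounts) -> np.ndarray:
    """F_new(t) = N_n(t)/N(t) * 100 per interval (indexed by session t >= 1)."""
    curr = counts.N[1:]
    if np.any(curr == 0):
        raise ValueError("new fraction undefined: empty current session")
    return counts.N_n[1:] / curr * 100.0


@dataclass
class TurnoverStats:
    """Headline turnover fractions (percent) of one dendrite."""

    counts: SessionCounts
    F_s: np.ndarray = field(init=False)
    F_lost: np.ndarray = field(init=False)
    F_new: np.ndarray = field(init=False)

    def __post_init__(self):
        self.F_s = survival_fraction(self.counts)
        self.F_lost = lost_fraction(self.counts)
        self.F_new = new_fraction(self.counts)

    def to_frame(self, session_days=None) -> pd.DataFrame:
        c = self.counts
        days = session_days or list(range(c.n_sessions))
        return pd.DataFrame(
            {
                "dendrite_id": c.dendrite_id,
                "day": days,
                "N": c.N,
                "N_r": c.N_r,
                "N_L": c.N_L,
                "N_n": c.N_n,
                "F_s_pct": self.F_s,
                "F_lost_pct": np.concatenate([[np.nan], self.F_lost]),
                "F_new_pct": np.concatenate([[np.nan], self.F_new]),
            }
        )


def aggregate_dendrites(values) -> tuple:
    """Across-dendrite mean +/- sem (the dendrite is the unit of analysis).

    With a single dendrite the sem is undefined and returned as NaN with a
    warning.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no dendrites to aggregate")
    mean = float(v.mean())
    if v.size == 1:
        warnings.warn("sem undefined for a single dendrite", stacklevel=2)
        return mean, float("nan")
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    return mean, sem
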