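"""Ground-truth dendrite/spine scenes and their evolution across sessions.

A scene is a straight stretch of basal dendrite (a cylinder of radius ``R``
along the x axis) carrying dendritic spines. Each spine protrudes radially
at an azimuth measured in the y-z plane (0 = along the optical z axis,
pi/2 = in the focal plane), with a cylindrical neck and a spherical head.
Head volume follows the spherical convention V = (pi/6) * d_max**3.

Across imaging sessions spines are lost with a size-dependent probability
(small spines are less stable) and new, small-biased spines appear at a
fixed rate per micrometer, so that density stays stationary. Spine
identities persist between sessions; a lost identity never returns.

All lengths are micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import as_rng

ALIVE = "alive"

#: exact column order of the per-spine CSV interchange format
CSV_COLUMNS = [
    "spine_id",
    "session",
    "x_pos_um",
    "azimuth_rad",
    "length_um",
    "neck_diam_um",
    "head_diam_max_um",
    "head_vol_um3",
    "born_session",
    "died_session",
]


def head_volume_from_diameter(d_max: float) -> float:
    """Spherical-head volume (um^3) from the maximum head diameter (um)."""
    return np.pi / 6.0 * d_max**3


@dataclass
class Spine:
    """One dendritic spine: geometry plus lifetime bookkeeping.

    ``died_session`` is the first session index at which the spine is
    absent, or ``"alive"`` while it persists.
    """

    spine_id: str
    x_pos: float
    azimuth: float
    length: float
    neck_diameter: float
    head_diameter_max: float
    head_volume: float = None  # type: ignore[assignment]
    born_session: int = 0
    died_session: "int | str" = ALIVE

    def __post_init__(self):
        if self.head_volume is None:
            self.head_volume = head_volume_from_diameter(self.head_diameter_max)
        if not self.length > 0:
            raise ValueError(f"spine length must be positive, got {self.length}")
        if not 0 <= self.azimuth < 2 * np.pi:
            self.azimuth = float(np.mod(self.azimuth, 2 * np.pi))
        if self.neck_diameter > self.head_diameter_max + 1e-12:
            raise ValueError(
                "neck diameter exceeds maximum head diameter "
                f"({self.neck_diameter} > {self.head_diameter_max})"
            )
        if self.died_session != ALIVE and self.born_session > self.died_session:
            raise ValueError("born_session must not exceed died_session")

    @property
    def head_radius(self) -> float:
        return self.head_diameter_max / 2.0


@dataclass
class MorphParams:
    """Lognormal morphology distributions (medians in um, sigma in log-space).

    Defaults put the median head volume at ~0.025 um^3 and the median neck
    at 150 nm, the scale seen on hippocampal basal dendrites.
    """

    head_diam_median: float = 0.36
    head_diam_sigma: float = 0.45
    neck_diam_median: float = 0.15
    neck_diam_sigma: float = 0.30
    length_median: float = 1.0
    length_sigma: float = 0.35


@dataclass
class TurnoverParams:
    """Size-dependent per-interval turnover.

    Survival probability of a spine with head volume V (um^3) is the
    logistic s(V) = 1 / (1 + exp(-(loss_a + loss_b * log10 V))); with
    loss_b >= 0 larger spines are at least as stable as small ones. The
    defaults give a mean per-interval loss of ~21% under the default
    morphology and, with ``gain_rate`` = 0.60 new spines per um per
    interval, a stationary density near 3 spines/um.
    """

    loss_a: float = 4.884
    loss_b: float = 2.0
    gain_rate: float = 0.60
    newborn_head_median: float = 0.30
    newborn_head_sigma: float = 0.40
    position_jitter: float = 0.0  # per-session sd of x_pos jitter, um

    def __post_init__(self):
        if self.loss_b < 0:
            raise ValueError("loss_b must be >= 0 (larger spines at least as stable)")
        if self.gain_rate < 0:
            raise ValueError("gain_rate must be >= 0")

    def survival_prob(self, head_volume):
        """Per-interval survival probability for head volume(s) in um^3."""
        v = np.asarray(head_volume, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.loss_a + self.loss_b * np.log10(v))))


@dataclass
class DendriteScene:
    """A dendrite at one imaging session with the spines alive on it."""

    dendrite_radius: float
    dendrite_length: float
    session_index: int
    spines: list = field(default_factory=list)
    dendrite_id: str = "d0"

    def __post_init__(self):
        if not self.dendrite_radius > 0:
            raise ValueError("dendrite_radius must be positive")
        if not self.dendrite_length > 0:
            raise ValueError("dendrite_length must be positive")
        for sp in self.spines:
            if not 0 <= sp.x_pos <= self.dendrite_length:
                raise ValueError(f"spine {sp.spine_id} lies outside the dendrite")

    def __len__(self) -> int:
        return len(self.spines)

    @property
    def true_density(self) -> float:
        return len(self.spines) / self.dendrite_length

    def spine_ids(self) -> set:
        return {sp.spine_id for sp in self.spines}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "spine_id": sp.spine_id,
                "session": self.session_index,
                "x_pos_um": sp.x_pos,
                "azimuth_rad": sp.azimuth,
                "length_um": sp.length,
                "neck_diam_um": sp.neck_diameter,
                "head_diam_max_um": sp.head_diameter_max,
                "head_vol_um3": sp.head_volume,
                "born_session": sp.born_session,
                "died_session": str(sp.died_session),
            }
            for sp in self.spines
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass
class SceneSeries:
    """Ordered scenes of one dendrite across sessions, sharing spine ids."""

    scenes: list
    session_days: tuple = (0, 2, 4)

    def __post_init__(self):
        if len(self.scenes) != len(self.session_days):
            raise ValueError("one session day per scene required")

    def __len__(self) -> int:
        return len(self.scenes)

    @property
    def dendrite_id(self) -> str:
        return self.scenes[0].dendrite_id

    @property
    def dendrite_length(self) -> float:
        return self.scenes[0].dendrite_length

    def presence(self) -> dict:
        """spine_id -> sorted list of session indices at which it is alive."""
        seen: dict = {}
        for i, sc in enumerate(self.scenes):
            for sp in sc.spines:
                seen.setdefault(sp.spine_id, []).append(i)
        return seen

    def spine_lookup(self) -> dict:
        """spine_id -> Spine (latest instance)."""
        out: dict = {}
        for sc in self.scenes:
            for sp in sc.spines:
                out[sp.spine_id] = sp
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([sc.to_frame() for sc in self.scenes], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sample_spine(rng, dendrite_length, morph: MorphParams, dendrite_id,
                  session, index) -> Spine:
    head = rng.lognormal(np.log(morph.head_diam_median), morph.head_diam_sigma)
    neck = rng.lognormal(np.log(morph.neck_diam_median), morph.neck_diam_sigma)
    neck = min(neck, head)  # necks never wider than the head
    length = rng.lognormal(np.log(morph.length_median), morph.length_sigma)
    return Spine(
        spine_id=f"{dendrite_id}-s{session}-{index:05d}",
        x_pos=float(rng.uniform(0.0, dendrite_length)),
        azimuth=float(rng.uniform(0.0, 2 * np.pi)),
        length=float(length),
        neck_diameter=float(neck),
        head_diameter_max=float(head),
        born_session=session,
    )


def generate_scene(
    density_true: float,
    dendrite_length: float,
    radius: float = 0.35,
    morph: MorphParams | None = None,
    seed=None,
    session_index: int = 0,
    dendrite_id: str = "d0",
) -> DendriteScene:
    """Sample a ground-truth scene.

    Spine count is Poisson(density_true * dendrite_length); positions are
    uniform along the dendrite and azimuths uniform on [0, 2*pi) — the
    azimuthal uniformity underpinning the blind-zone extrapolation.

    Parameters
    ----------
    density_true : spines per um of dendrite (>= 0).
    dendrite_length : um, at least 5.
    radius : dendrite shaft radius in um.
    """
    if density_true < 0:
        raise ValueError("density_true must be non-negative")
    if dendrite_length < 5:
        raise ValueError("dendrite_length must be at least 5 um")
    morph = morph or MorphParams()
    rng = as_rng(seed, "scene")
    n = int(rng.poisson(density_true * dendrite_length))
    spines = [
        _sample_spine(rng, dendrite_length, morph, dendrite_id, session_index, i)
        for i in range(n)
    ]
    return DendriteScene(radius, dendrite_length, session_index, spines, dendrite_id)


def evolve_scene(
    scene: DendriteScene,
    params: TurnoverParams | None = None,
    seed=None,
) -> DendriteScene:
    """Advance a scene by one inter-session interval.

    Each spine survives independently with probability s(head_volume);
    lost spines have ``died_session`` stamped with the new session index.
    New spines arrive as Poisson(gain_rate * dendrite_length) with
    small-biased head sizes. Survivors keep their identity and (up to
    optional jitter) their position.
    """
    params = params or TurnoverParams()
    rng = as_rng(seed, "evolve")
    next_session = scene.session_index + 1

    survivors = []
    for sp in scene.spines:
        if rng.random() < params.survival_prob(sp.head_volume):
            if params.position_jitter > 0:
                x = float(
                    np.clip(
                        sp.x_pos + rng.normal(0.0, params.position_jitter),
                        0.0,
                        scene.dendrite_length,
                    )
                )
                survivors.append(replace(sp, x_pos=x))
            else:
                survivors.append(sp)
        else:
            sp.died_session = next_session

    morph = MorphParams(
        head_diam_median=params.newborn_head_median,
        head_diam_sigma=params.newborn_head_sigma,
    )
    n_new = int(rng.poisson(params.gain_rate * scene.dendrite_length))
    newborns = [
        _sample_spine(rng, scene.dendrite_length, morph, scene.dendrite_id,
                      next_session, i)
        for i in range(n_new)
    ]
    return DendriteScene(
        scene.dendrite_radius,
        scene.dendrite_length,
        next_session,
        survivors + newborns,
        scene.dendrite_id,
    )


def generate_series(
    n_sessions: int = 3,
    density_true: float = 3.0,
    dendrite_length: float = 20.0,
    radius: float = 0.35,
    morph: MorphParams | None = None,
    turnover: TurnoverParams | None = None,
    seed=None,
    session_days: tuple | None = None,
    dendrite_id: str = "d0",
) -> SceneSeries:
    """Chain generate_scene and evolve_scene into a longitudinal series.

    Default session days are 0, 2 and 4 (three sessions, 2-day intervals).
    """
    if n_sessions < 2:
        raise ValueError("a series needs at least 2 sessions")
    if session_days is None:
        session_days = tuple(2 * i for i in range(n_sessions))
    if len(session_days) != n_sessions or any(
        b <= a for a, b in zip(session_days, session_days[1:])
    ):
        raise ValueError("session_days must be strictly increasing, one per session")
    turnover = turnover or TurnoverParams()
    rng = as_rng(seed, "series")
    scenes = [
        generate_scene(density_true, dendrite_length, radius, morph,
                       seed=rng, session_index=0, dendrite_id=dendrite_id)
    ]
    for _ in range(n_sessions - 1):
        scenes.append(evolve_scene(scenes[-1], turnover, seed=rng))
    return SceneSeries(scenes, tuple(session_days))


def scene_from_frame(df: pd.DataFrame, radius: float, dendrite_length: float,
                     session: int, dendrite_id: str = "d0") -> DendriteScene:
    sub = df[df["session"] == session]
    spines = [
        Spine(
            spine_id=str(r.spine_id),
            x_pos=float(r.x_pos_um),
            azimuth=float(r.azimuth_rad),
            length=float(r.length_um),
            neck_diameter=float(r.neck_diam_um),
            head_diameter_max=float(r.head_diam_max_um),
            head_volume=float(r.head_vol_um3),
            born_session=int(r.born_session),
            died_session=ALIVE if str(r.died_session) == ALIVE
            else int(r.died_session),
        )
        for r in sub.itertuples()
    ]
    return DendriteScene(radius, dendrite_length, session, spines, dendrite_id)


def series_from_csv(path, radius: float, dendrite_length: float,
                    session_days: tuple = (0, 2, 4),
                    dendrite_id: str = "d0") -> SceneSeries:
    """Read a per-spine CSV (one row per spine per session) back into a series."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scene CSV missing columns: {sorted(missing)}")
    sessions = sorted(df["session"].unique())
    scenes = [
        scene_from_frame(df, radius, dendrite_length, s, dendrite_id)
        for s in sessions
    ]
    return SceneSeries(scenes, tuple(session_days))
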