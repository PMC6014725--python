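"""Deterministic geometric observer implementing the manual counting rules.

Two rules decide what a human scrolling through a z-stack would count:

1. Protrusion threshold: a spine is counted only if it extends laterally
   beyond the dendritic shaft silhouette by more than ``d_min`` (200 nm by
   default). With the spine tip at radius R + length and azimuth phi, the
   projected protrusion is e = (R + length) * |sin phi| - R; spines near the
   optical axis (the "blind zone") never clear the threshold because only
   lateral, not axial, resolution is improved.

2. Merge rule: detected spines on the same side of the shaft whose axial
   positions differ by less than the lateral resolution appear as one spine
   (transitive closure), which is why diffraction-limited imaging undercounts
   clustered spines.

The observer runs on ground-truth geometry, which makes the detection model
explicit and testable; rendered stacks serve for visual validation and FWHM
measurements, not for counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import ImagingConfig
from .scene import DendriteScene

DETECTED = "detected"
MASKED_AXIAL = "masked_axial"
BELOW_THRESHOLD = "below_threshold"
MERGED = "merged"

#: |sin(azimuth)| below which an undetected spine is labelled masked_axial
#: rather than below_threshold. Labelling only — both count as undetected.
_AXIAL_SPLIT = 0.5


def lateral_protrusion(radius: float, length: float, azimuth) -> float:
    """Projected protrusion beyond the shaft silhouette, in um (may be < 0)."""
    return (radius + length) * np.abs(np.sin(azimuth)) - radius


def detectable(spine, radius: float, config: ImagingConfig) -> str:
    """Apply the protrusion rule to one spine; returns a verdict label."""
    e = lateral_protrusion(radius, spine.length, spine.azimuth)
    if e >= config.d_min * 1e-3:
        return DETECTED
    if abs(np.sin(spine.azimuth)) < _AXIAL_SPLIT:
        return MASKED_AXIAL
    return BELOW_THRESHOLD


@dataclass
class ObservedSpine:
    """One spine as reported by the observer (possibly a merged cluster)."""

    spine_id: str            # representative: the largest head in the cluster
    x_obs: float             # head-volume-weighted mean position, um
    side: int                # sign of sin(azimuth)
    member_ids: tuple = ()   # all ground-truth ids folded into this report


@dataclass
class ObservedScene:
    """Observer output: detections plus a verdict for every true spine."""

    dendrite_id: str
    session_index: int
    dendrite_length: float
    config: ImagingConfig
    detected: list = field(default_factory=list)
    verdicts: dict = field(default_factory=dict)     # spine_id -> verdict
    merged_into: dict = field(default_factory=dict)  # member id -> representative

    def __len__(self) -> int:
        return len(self.detected)

    @property
    def observed_density(self) -> float:
        return len(self.detected) / self.dendrite_length

    def verdict_counts(self) -> dict:
        out: dict = {}
        for v in self.verdicts.values():
            out[v] = out.get(v, 0) + 1
        return out

    def positions(self) -> list:
        """(spine_id, x_obs) pairs of the detections, sorted by position."""
        return sorted(((d.spine_id, d.x_obs) for d in self.detected),
                      key=lambda t: (t[1], t[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        x_of = {d.spine_id: d.x_obs for d in self.detected}
        for sid, verdict in self.verdicts.items():
            rows.append(
                {
                    "spine_id": sid,
                    "session": self.session_index,
                    "verdict": verdict,
                    "observed_x_um": x_of.get(sid, np.nan),
                    "merged_into": self.merged_into.get(sid, ""),
                }
            )
        return pd.DataFrame(
            rows, columns=["spine_id", "session", "verdict", "observed_x_um",
                           "merged_into"]
        )


def observe_scene(scene: DendriteScene, config: ImagingConfig) -> ObservedScene:
    """Run both counting rules over a scene; fully deterministic.

    Merging is the transitive closure of "same side and |dx| < merge
    distance" over provisionally detected spines. The cluster is reported
    once, at the head-volume-weighted mean position, under the id of its
    largest head (ties broken toward smaller x).
    """
    obs = ObservedScene(
        dendrite_id=scene.dendrite_id,
        session_index=scene.session_index,
        dendrite_length=scene.dendrite_length,
        config=config,
    )
    provisional = []
    for sp in scene.spines:
        v = detectable(sp, scene.dendrite_radius, config)
        obs.verdicts[sp.spine_id] = v
        if v == DETECTED:
            provisional.append(sp)

    merge_um = config.merge_distance_nm * 1e-3
    for side in (+1, -1):
        group = sorted(
            (sp for sp in provisional if np.sign(np.sin(sp.azimuth)) == side),
            key=lambda sp: (sp.x_pos, sp.spine_id),
        )
        # in 1-D the transitive closure is a chain of consecutive neighbours
        clusters: list = []
        for sp in group:
            if clusters and sp.x_pos - clusters[-1][-1].x_pos < merge_um:
                clusters[-1].append(sp)
            else:
                clusters.append([sp])
        for members in clusters:
            rep = max(members,
                      key=lambda sp: (sp.head_diameter_max, -sp.x_pos))
            w = np.array([sp.head_volume for sp in members])
            x = np.array([sp.x_pos for sp in members])
            obs.detected.append(
                ObservedSpine(
                    spine_id=rep.spine_id,
                    x_obs=float(np.average(x, weights=w)),
                    side=side,
                    member_ids=tuple(sp.spine_id for sp in members),
                )
            )
            for sp in members:
                if sp is not rep:
                    obs.verdicts[sp.spine_id] = MERGED
                    obs.merged_into[sp.spine_id] = rep.spine_id
    obs.detected.sort(key=lambda d: (d.x_obs, d.spine_id))
    return obs


def spine_density(obj) -> float:
    """Spines per micrometer, for a ground-truth scene or an observation."""
    if isinstance(obj, ObservedScene):
        n, length = len(obj.detected), obj.dendrite_length
    elif isinstance(obj, DendriteScene):
        n, length = len(obj.spines), obj.dendrite_length
    else:
        raise TypeError(f"cannot compute a density for {type(obj).__name__}")
    if length <= 0:
        raise ValueError("dendrite length must be positive")
    return n / length
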