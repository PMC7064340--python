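"""Synthetic inputs: designed tracts, synthetic sagittal profiles, song scenarios.

Everything the pipeline consumes can be generated here with known ground
truth, emulating the study conditions of Sygyt-style overtone singing:

* a "designed" neutral-ish area function with the two controlling
  constrictions — oral (CO, near the alveolar ridge, ~14 cm from the
  glottis) and pharyngeal (CP, near the uvula) — plus a sublingual
  expansion just anterior to CO;
* synthetic midsagittal profiles built around a known centerline, the
  oracle for centerline extraction;
* parametric song scenarios (f0 contour, focused segments, fast 40–60 ms
  transitions) matching the timing and frequency ranges reported for
  Tuvan singers (f0 ≈ 140–165 Hz, focus in 1.5–2 kHz, optional second
  focus at 3–3.5 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AreaFunction,
    CrossSectionSeries,
    SagittalProfile,
    K_CIRCULAR,
)

__all__ = [
    "TractDesignParams",
    "Segment",
    "SongScenario",
    "make_designed_area_function",
    "make_synthetic_profile",
    "make_song_scenario",
]


@dataclass(frozen=True)
class TractDesignParams:
    """Parameters of the designed tract (lengths/positions in cm, areas cm^2).

    ``cp_position < co_position``: the pharyngeal constriction sits
    glottis-ward of the alveolar-ridge constriction.
    """

    L: float = 17.5
    A_rest: float = 3.0
    n_sections: int = 44
    co_position: float = 14.0  # alveolar-ridge constriction
    co_area: float = 0.8
    cp_position: float = 6.0  # uvular / upper-pharynx constriction
    cp_area: float = 1.6
    sublingual_position: float = 15.8  # expansion anterior to CO
    sublingual_expansion_area: float = 4.5
    lip_area: float = 0.6  # mouth opening at the lips (Sygyt: nearly closed)
    lip_taper_width: float = 0.8
    taper_width: float = 1.0  # Gaussian sigma of each feature, cm

    def __post_init__(self) -> None:
        for name in ("co_position", "cp_position", "sublingual_position"):
            v = getattr(self, name)
            if not 0 < v < self.L:
                raise ValueError(f"{name} must lie inside (0, L)")
        for name in ("A_rest", "co_area", "cp_area", "sublingual_expansion_area", "lip_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.cp_position < self.co_position:
            raise ValueError("cp_position must be glottis-ward of co_position")
        if self.co_position - self.cp_position < 2.0 * self.taper_width:
            raise ValueError("CO and CP supports overlap beyond taper limits")
        if self.taper_width <= 0:
            raise ValueError("taper_width must be positive")


def make_designed_area_function(p: TractDesignParams = TractDesignParams()) -> AreaFunction:
    """Build the designed neutral-ish area function.

    A cosine-tapered baseline of area ``A_rest`` (narrow at the glottis,
    opening over the first ~2 cm) is modified in log-area by Gaussian
    bumps: constrictions at CP and CO and an expansion anterior to CO.
    The default parameters give well-separated formants (F3 - F2 well
    above 500 Hz) — effectively a neutral vowel.
    """
    x = np.linspace(0.0, p.L, p.n_sections)
    # narrow glottal end opening smoothly to A_rest
    taper = 0.25 + 0.75 * 0.5 * (1.0 - np.cos(np.pi * np.minimum(x / 2.0, 1.0)))
    log_a = np.log(p.A_rest * taper)

    def bump(pos: float, area: float) -> np.ndarray:
        return np.log(area / p.A_rest) * np.exp(-0.5 * ((x - pos) / p.taper_width) ** 2)

    log_a += bump(p.cp_position, p.cp_area)
    log_a += bump(p.co_position, p.co_area)
    log_a += bump(p.sublingual_position, p.sublingual_expansion_area)
    A = np.exp(log_a)
    # taper toward a modest mouth opening at the lips
    blend = np.exp(-0.5 * ((x - p.L) / p.lip_taper_width) ** 2)
    A = A * (p.lip_area / A[-1]) ** blend
    return AreaFunction(x=x, A=A)


def make_synthetic_profile(
    af: AreaFunction, curvature_deg: float = 0.0
) -> tuple[SagittalProfile, CrossSectionSeries]:
    """Synthetic midsagittal profile for a known area function.

    The centerline is a straight line (``curvature_deg = 0``) or a circular
    arc bending by the given angle over the tract length; the inner/outer
    contours are offset by ``±D(x)/2`` along the local normal, with
    ``D = sqrt(A / k)`` under the circular-section rule (alpha = 2).
    Returns the profile together with the ground-truth cross-section series.
    """
    D = np.sqrt(af.A / K_CIRCULAR)
    L = af.L
    if abs(curvature_deg) < 1e-9:
        center = np.column_stack([af.x, np.zeros_like(af.x)])
        normals = np.tile([0.0, 1.0], (len(af.x), 1))
    else:
        theta_total = np.deg2rad(curvature_deg)
        R = L / abs(theta_total)
        if R - np.max(D) / 2.0 <= 0:
            raise ValueError("bend too tight: inner contour would self-intersect")
        theta = af.x / R * np.sign(theta_total)
        center = np.column_stack([R * np.sin(np.abs(theta)), np.sign(theta_total) * R * (1 - np.cos(theta))])
        # outward normal of the arc
        normals = np.column_stack([-np.sin(np.abs(theta)) * np.sign(theta_total), np.cos(theta)])
    inner = center - 0.5 * D[:, None] * normals
    outer = center + 0.5 * D[:, None] * normals
    profile = SagittalProfile(inner=inner, outer=outer)
    truth = CrossSectionSeries(centerline=center, x=af.x.copy(), D=D)
    return profile, truth


@dataclass(frozen=True)
class Segment:
    """One scenario segment: from t_start until the next segment starts."""

    t_start: float
    state: str  # "normal" | "focused"
    focus_hz: float | None = None
    second_focus_hz: float | None = None


@dataclass
class SongScenario:
    """Parametric ground-truth timeline for synthesis and recovery tests."""

    duration: float
    f0_hz: float
    segments: list[Segment] = field(default_factory=list)
    transition_ms: float = 50.0
    vibrato_rate_hz: float = 0.0
    vibrato_depth_cents: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.f0_hz <= 0:
            raise ValueError("duration and f0 must be positive")
        starts = [s.t_start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments must be ordered by t_start")

    def focus_weight(self, t: np.ndarray) -> np.ndarray:
        """Focused-state weight in [0, 1] at times t, with linear ramps."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        w = np.zeros_like(t)
        ramp = self.transition_ms / 1000.0
        for k, seg in enumerate(self.segments):
            t_end = (
                self.segments[k + 1].t_start if k + 1 < len(self.segments) else self.duration
            )
            target = 1.0 if seg.state == "focused" else 0.0
            if k == 0:
                w = np.where(t < t_end, target, w)
            else:
                # ramp from the previous target over [t_start, t_start+ramp]
                prev = 1.0 if self.segments[k - 1].state == "focused" else 0.0
                frac = np.clip((t - seg.t_start) / max(ramp, 1e-9), 0.0, 1.0)
                seg_w = prev + (target - prev) * frac
                w = np.where((t >= seg.t_start) & (t < t_end), seg_w, w)
        return w

    def transition_times(self) -> list[float]:
        """Times where the state changes (start of each ramp)."""
        out = []
        for prev, cur in zip(self.segments, self.segments[1:]):
            if prev.state != cur.state:
                out.append(cur.t_start)
        return out


def make_song_scenario(
    style: str = "sygyt",
    f0_hz: float = 150.0,
    duration: float = 4.0,
    seed: int = 0,
) -> SongScenario:
    """Seeded scenario generator for the three emulated song styles.

    ``normal`` holds the drone with no focused segment; ``sygyt`` places one
    normal→focused transition with a focus frequency drawn from 1.5–2 kHz
    (snapped to the nearest harmonic of f0); ``sygyt_double`` adds a second,
    static focus drawn from 3–3.5 kHz.
    """
    rng = np.random.default_rng(seed)
    if style == "normal":
        segments = [Segment(0.0, "normal")]
    elif style in ("sygyt", "sygyt_double"):
        t_tr = float(rng.uniform(0.35, 0.65) * duration)
        focus = float(rng.uniform(1500.0, 2000.0))
        focus = round(focus / f0_hz) * f0_hz  # the singer amplifies a harmonic
        second = float(rng.uniform(3000.0, 3500.0)) if style == "sygyt_double" else None
        segments = [
            Segment(0.0, "normal"),
            Segment(t_tr, "focused", focus_hz=focus, second_focus_hz=second),
        ]
    else:
        raise ValueError(f"unknown style {style!r}")
    return SongScenario(
        duration=duration,
        f0_hz=f0_hz,
        segments=segments,
        transition_ms=50.0,
        seed=seed,
    )
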