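"""Calibrated scenario presets for the synthetic trajectory generator.

Each preset bundles the kinetic and structural parameters of one simulated
condition: the applied-field geometry, the expected number of complete
outward permeations per 3.2 us, the stationary probability of the trapped
"exotic" occupancy states, the direct vs soft knock-on mechanism mix, and
per-residue phi-dihedral circular distributions for the filter residues
THR75..GLY79.

Calibration anchors (per 3.2 us): 587 events at theta = 0 deg, 374 at
theta = 90 deg, 471 without a field (the count whose single-channel current
is 23.6 pA), exotic-state fraction 0.31 at theta = 90 deg and <= 0.15 for
every other condition.  The theta = 30/45/60 deg event counts (550/520/460)
are monotone interpolations between the calibrated endpoints; they are
package constants, not measured values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .sf_model import AppliedField

__all__ = [
    "VonMisesMixture",
    "PresetParams",
    "PRESET_NAMES",
    "SF_RESIDUES",
    "get_preset",
    "derive_normal_rate",
]

SF_RESIDUES = ("THR75", "VAL76", "GLY77", "TYR78", "GLY79")


@dataclass(frozen=True)
class VonMisesMixture:
    """Mixture of von Mises components on the circle.

    ``components`` is a tuple of (mean_deg, kappa, weight); weights must sum
    to 1.  Angles are reported in (-180, 180].
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if any(c[1] < 0 for c in self.components):
            raise ValueError("concentration kappa must be >= 0")

    def sample(self, rng: np.random.Generator, size: int | tuple[int, ...]) -> np.ndarray:
        """Draw angles in degrees, wrapped to (-180, 180]."""
        size_arr = np.empty(size)
        n = size_arr.size
        weights = np.array([c[2] for c in self.components])
        which = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for k, (mu, kappa, _) in enumerate(self.components):
            sel = which == k
            if sel.any():
                draws = rng.vonmises(np.radians(mu), kappa, size=int(sel.sum()))
                out[sel] = np.degrees(draws)
        # numpy wraps to [-pi, pi]; move -180 to +180 for the principal interval
        out[out <= -180.0] += 360.0
        return out.reshape(size_arr.shape)

    def to_dict(self) -> list:
        return [list(c) for c in self.components]

    @classmethod
    def from_dict(cls, data) -> "VonMisesMixture":
        return cls(tuple(tuple(float(x) for x in c) for c in data))

    @classmethod
    def single(cls, mean_deg: float, kappa: float) -> "VonMisesMixture":
        return cls(((mean_deg, kappa, 1.0),))


#: Resting SF occupancy during NORMAL regime, ordered S4..S0.  The stable
#: conduction ground state keeps K+ at S4 and S2; a destabilised filter
#: (theta = 90 deg) holds only the inner S4 ion, which is what depletes the
#: S2/S1/S0 density there.
RESTING_S4_S2 = ("K", "EMPTY", "K", "EMPTY", "EMPTY")
RESTING_S4 = ("K", "EMPTY", "EMPTY", "EMPTY", "EMPTY")


@dataclass(frozen=True)
class PresetParams:
    """Ground-truth parameters of one simulated scenario."""

    name: str
    field: AppliedField | None
    expected_events: float
    exotic_fraction: float
    mechanism_direct_prob: float
    phi: dict[str, VonMisesMixture]
    exotic_dwell_mean: float = 5.0  # ns
    duration_us: float = 3.2
    frame_interval_ns: float = 0.05
    normal_pattern: tuple[str, str, str, str, str] = RESTING_S4_S2

    def __post_init__(self) -> None:
        if self.expected_events < 0:
            raise ValueError("expected_events must be >= 0")
        if not (0.0 <= self.exotic_fraction < 1.0):
            raise ValueError("exotic_fraction must lie in [0, 1)")
        if not (0.0 <= self.mechanism_direct_prob <= 1.0):
            raise ValueError("mechanism_direct_prob must lie in [0, 1]")
        if self.exotic_dwell_mean <= 0:
            raise ValueError("exotic_dwell_mean must be positive")
        if self.duration_us <= 0:
            raise ValueError("duration must be positive")

    @property
    def duration_ns(self) -> float:
        return self.duration_us * 1000.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "field": None if self.field is None else self.field.to_dict(),
            "expected_events": self.expected_events,
            "exotic_fraction": self.exotic_fraction,
            "mechanism_direct_prob": self.mechanism_direct_prob,
            "exotic_dwell_mean": self.exotic_dwell_mean,
            "duration_us": self.duration_us,
            "frame_interval_ns": self.frame_interval_ns,
            "normal_pattern": list(self.normal_pattern),
            "phi": {res: mix.to_dict() for res, mix in self.phi.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PresetParams":
        return cls(
            name=d["name"],
            field=None if d.get("field") is None else AppliedField.from_dict(d["field"]),
            expected_events=float(d["expected_events"]),
            exotic_fraction=float(d["exotic_fraction"]),
            mechanism_direct_prob=float(d["mechanism_direct_prob"]),
            exotic_dwell_mean=float(d.get("exotic_dwell_mean", 5.0)),
            duration_us=float(d.get("duration_us", 3.2)),
            frame_interval_ns=float(d.get("frame_interval_ns", 0.05)),
            normal_pattern=tuple(d.get("normal_pattern", RESTING_S4_S2)),
            phi={res: VonMisesMixture.from_dict(m) for res, m in d["phi"].items()},
        )


_STABLE_THR75 = VonMisesMixture.single(-65.0, 60.0)
_STABLE_VAL76 = VonMisesMixture.single(-120.0, 60.0)
_GLY77_TIGHT = VonMisesMixture.single(-80.0, 40.0)
_GLY77_MID = VonMisesMixture.single(-80.0, 15.0)
_GLY77_BROAD = VonMisesMixture(((-80.0, 8.0, 0.6), (70.0, 4.0, 0.4)))
_TYR78_TIGHT = VonMisesMixture.single(-120.0, 40.0)
_TYR78_BROAD = VonMisesMixture.single(-120.0, 12.0)
_GLY79_TIGHT = VonMisesMixture.single(80.0, 40.0)
_GLY79_BROAD = VonMisesMixture.single(80.0, 12.0)


def _phi_set(gly77: VonMisesMixture, broadened: bool) -> dict[str, VonMisesMixture]:
    # THR75/VAL76 (the S4/S3 cages the ion reaches first) are identical and
    # highly concentrated in every scenario; TYR78/GLY79 broaden only in the
    # unstable conditions (no field, theta = 90 deg).
    return {
        "THR75": _STABLE_THR75,
        "VAL76": _STABLE_VAL76,
        "GLY77": gly77,
        "TYR78": _TYR78_BROAD if broadened else _TYR78_TIGHT,
        "GLY79": _GLY79_BROAD if broadened else _GLY79_TIGHT,
    }


def _field(theta: float) -> AppliedField:
    return AppliedField(amplitude=0.4, frequency=51.87, theta=theta)


_PRESETS: dict[str, PresetParams] = {
    "no_field": PresetParams(
        name="no_field",
        field=None,
        expected_events=471,  # count whose current over 3.2 us is 23.6 pA
        exotic_fraction=0.12,
        mechanism_direct_prob=0.90,
        phi=_phi_set(_GLY77_BROAD, broadened=True),
    ),
    "theta0": PresetParams(
        name="theta0",
        field=_field(0.0),
        expected_events=587,
        exotic_fraction=0.10,
        mechanism_direct_prob=0.95,
        phi=_phi_set(_GLY77_TIGHT, broadened=False),
    ),
    "theta30": PresetParams(
        name="theta30",
        field=_field(30.0),
        expected_events=550,
        exotic_fraction=0.10,
        mechanism_direct_prob=0.90,
        phi=_phi_set(_GLY77_MID, broadened=False),
    ),
    "theta45": PresetParams(
        name="theta45",
        field=_field(45.0),
        expected_events=520,
        exotic_fraction=0.10,
        mechanism_direct_prob=0.90,
        phi=_phi_set(_GLY77_MID, broadened=False),
    ),
    "theta60": PresetParams(
        name="theta60",
        field=_field(60.0),
        expected_events=460,
        exotic_fraction=0.10,
        mechanism_direct_prob=0.90,
        phi=_phi_set(_GLY77_MID, broadened=False),
    ),
    "theta90": PresetParams(
        name="theta90",
        field=_field(90.0),
        expected_events=374,
        exotic_fraction=0.31,
        mechanism_direct_prob=0.69,
        phi=_phi_set(_GLY77_BROAD, broadened=True),
        normal_pattern=RESTING_S4,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> PresetParams:
    """Return the calibrated preset for a named scenario.

    Valid names: ``no_field, theta0, theta30, theta45, theta60, theta90``.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def derive_normal_rate(params: PresetParams) -> float:
    """Permeation completion rate (events per us) inside the NORMAL regime.

    Exotic episodes suppress permeation, so to realise ``expected_events``
    over the whole run the normal-regime rate must be inflated to
    expected_events / (duration * (1 - exotic_fraction)).
    """
    if params.exotic_fraction >= 1.0:
        raise ValueError("exotic_fraction must be < 1 to derive a finite rate")
    return params.expected_events / (params.duration_us * (1.0 - params.exotic_fraction))
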