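"""Coefficient catalogue for the cadmium toxicokinetic model.

The model is a linear multi-compartment scheme (three blood pools, liver,
kidney, other tissue, with urinary/fecal/exhaled elimination) integrated as
explicit daily difference equations.  All coefficients live in a single
:class:`TKParameters` object loaded from a strict YAML catalogue; nothing in
the simulator carries hidden constants.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TKParameters",
    "ConfigurationError",
    "StabilityError",
    "default_parameters",
    "TRANSFER_KEYS",
    "COMPARTMENT_OUTFLOWS",
]


class ConfigurationError(ValueError):
    """A parameter catalogue is missing keys, has unknown keys, or bad values."""


class StabilityError(ValueError):
    """A compartment's total daily outflow fraction exceeds 1 (explicit-step blow-up)."""


SEXES = ("male", "female")

#: The complete roster of first-order daily transfer fractions.
TRANSFER_KEYS = frozenset(
    {
        "k_B1B2", "k_B2B1", "k_B1B3", "k_B1L", "k_B1K", "k_B1T", "k_TB1",
        "k_B1F", "k_B3K", "k_B3U", "k_LB3", "k_LF", "k_KU", "k_KB1",
    }
)

#: Outgoing transfer coefficients per source compartment, used for the
#: explicit-step stability check (sum of outflows x timestep must be <= 1).
COMPARTMENT_OUTFLOWS = {
    "B1": ("k_B1B2", "k_B1B3", "k_B1L", "k_B1K", "k_B1T", "k_B1F"),
    "B2": ("k_B2B1",),
    "B3": ("k_B3K", "k_B3U"),
    "L": ("k_LB3", "k_LF"),
    "K": ("k_KU", "k_KB1"),
    "T": ("k_TB1",),
}


@dataclass
class TKParameters:
    """Full coefficient set of the compartment model.

    Parameters
    ----------
    absorption_gut_by_sex
        Fraction of cadmium reaching the gut that is absorbed into the fast
        blood pool, per sex (females absorb more, consistent with lower iron
        stores).
    absorption_lung
        Fraction of inhaled cadmium absorbed through the alveolar route.
    mucociliary_to_gut
        Fraction of inhaled cadmium cleared by the mucociliary escalator to
        the gut (then subject to gut absorption); the remainder of inhaled
        cadmium, ``1 - absorption_lung - mucociliary_to_gut``, is exhaled.
    transfer_coefficients
        First-order daily fractions (day^-1) between compartments; see
        :data:`TRANSFER_KEYS`.
    creatinine_curve
        Per sex, piecewise-linear ``[(age_years, g_per_day), ...]`` control
        points for daily urinary creatinine excretion.
    diet_age_scaling
        Piecewise-linear multiplier on the adult dietary intake as a function
        of age in years; 1.0 for adults.
    gain_scale_by_group
        Multiplicative calibration scale applied to model-predicted urinary
        cadmium per ``(locality, sex)`` group; default 1.0.  Set by the
        reverse-dosimetry anchoring step.
    timestep
        Integration step in days (default 1).
    """

    absorption_gut_by_sex: dict[str, float]
    absorption_lung: float
    mucociliary_to_gut: float
    transfer_coefficients: dict[str, float]
    creatinine_curve: dict[str, list[tuple[float, float]]]
    diet_age_scaling: list[tuple[float, float]]
    gain_scale_by_group: dict[tuple[str, str], float] = field(default_factory=dict)
    timestep: float = 1.0

    # memo of unanchored unit-intake simulations, keyed by
    # (kind, age_days, sex, start_age); safe because every field that feeds
    # the simulation is treated as frozen after validation (only
    # gain_scale_by_group, which is applied outside the memo, mutates).
    _gain_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for sex in SEXES:
            if sex not in self.absorption_gut_by_sex:
                raise ConfigurationError(f"missing gut absorption for sex {sex!r}")
        for name, value in [
            ("absorption_lung", self.absorption_lung),
            ("mucociliary_to_gut", self.mucociliary_to_gut),
            *((f"absorption.gut.{s}", v) for s, v in self.absorption_gut_by_sex.items()),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} = {value} is not a fraction in [0, 1]")
        if self.absorption_lung + self.mucociliary_to_gut > 1.0:
            raise ConfigurationError(
                "absorption_lung + mucociliary_to_gut exceeds 1: no inhaled mass left to exhale"
            )

        missing = TRANSFER_KEYS - self.transfer_coefficients.keys()
        if missing:
            raise ConfigurationError(f"missing transfer coefficient(s): {sorted(missing)}")
        unknown = self.transfer_coefficients.keys() - TRANSFER_KEYS
        if unknown:
            raise ConfigurationError(f"unknown transfer coefficient(s): {sorted(unknown)}")
        for key, value in self.transfer_coefficients.items():
            if value < 0.0:
                raise ConfigurationError(f"{key} = {value} must be non-negative")
        # upper bounds are enforced jointly per compartment below

        if self.timestep <= 0:
            raise ConfigurationError(f"timestep must be positive, got {self.timestep}")
        for comp, keys in COMPARTMENT_OUTFLOWS.items():
            total = sum(self.transfer_coefficients[k] for k in keys) * self.timestep
            if total > 1.0 + 1e-12:
                raise StabilityError(
                    f"compartment {comp}: total outgoing fraction {total:.4g} per step exceeds 1"
                )

        ages = np.arange(1.0, 101.0)
        for sex in SEXES:
            if sex not in self.creatinine_curve:
                raise ConfigurationError(f"missing creatinine curve for sex {sex!r}")
            if np.any(self.creatinine_for_age(ages, sex) <= 0):
                raise ConfigurationError(f"creatinine curve for {sex!r} is not positive on ages 1-100")

        scaling = self.diet_scaling_for_age(np.arange(0.0, 101.0))
        if np.any(scaling <= 0) or np.any(scaling > 1.0):
            raise ConfigurationError("diet_age_scaling must lie in (0, 1]")
        adult = self.diet_scaling_for_age(np.arange(18.0, 101.0))
        if not np.allclose(adult, 1.0):
            raise ConfigurationError("diet_age_scaling must equal 1 for ages >= 18")

    # -- curve evaluation ---------------------------------------------------
    def creatinine_for_age(self, age_years, sex: str):
        """Daily creatinine excretion (g/day) at ``age_years`` for ``sex``."""
        pts = np.asarray(self.creatinine_curve[sex], dtype=float)
        return np.interp(age_years, pts[:, 0], pts[:, 1])

    def diet_scaling_for_age(self, age_years):
        """Multiplier on the adult dietary intake at ``age_years``."""
        pts = np.asarray(self.diet_age_scaling, dtype=float)
        return np.interp(age_years, pts[:, 0], pts[:, 1])

    def gain_scale(self, locality: str, sex: str) -> float:
        return self.gain_scale_by_group.get((locality, sex), 1.0)

    def copy(self) -> "TKParameters":
        new = copy.deepcopy(self)
        new._gain_cache = dict(self._gain_cache)
        return new


def _require_mapping(node, name: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigurationError(f"section {name!r} must be a mapping")
    return node


def _pop(node: dict, key: str, section: str):
    if key not in node:
        raise ConfigurationError(f"missing key {section}.{key}")
    return node.pop(key)


def _check_empty(node: dict, section: str) -> None:
    if node:
        raise ConfigurationError(f"unknown key(s) in {section}: {sorted(node)}")


def default_parameters(config_source=None) -> TKParameters:
    """Load a :class:`TKParameters` from a YAML catalogue.

    ``config_source`` may be a path or an open text stream; ``None`` loads the
    packaged default catalogue.  The schema is strict: every coefficient is
    required and unknown keys are rejected, so a partial or misspelled
    catalogue fails loudly rather than silently mixing defaults.
    """
    if config_source is None:
        ref = importlib.resources.files("cdexposure.data") / "default_params.yaml"
        text = ref.read_text(encoding="utf-8")
    elif hasattr(config_source, "read"):
        text = config_source.read()
    else:
        with open(config_source, "r", encoding="utf-8") as fh:
            text = fh.read()

    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough context
        raise ConfigurationError(f"could not parse parameter config: {exc}") from exc
    raw = _require_mapping(raw, "<root>")

    absorption = _require_mapping(_pop(raw, "absorption", "<root>"), "absorption")
    gut = _require_mapping(_pop(absorption, "gut", "absorption"), "absorption.gut")
    gut_by_sex = {sex: float(_pop(gut, sex, "absorption.gut")) for sex in SEXES}
    _check_empty(gut, "absorption.gut")
    lung = float(_pop(absorption, "lung", "absorption"))
    muco = float(_pop(absorption, "mucociliary_to_gut", "absorption"))
    _check_empty(absorption, "absorption")

    transfers = _require_mapping(
        _pop(raw, "transfer_coefficients", "<root>"), "transfer_coefficients"
    )
    transfers = {str(k): float(v) for k, v in transfers.items()}

    creat = _require_mapping(_pop(raw, "creatinine_curve", "<root>"), "creatinine_curve")
    creat_curve = {
        sex: [(float(a), float(v)) for a, v in _pop(creat, sex, "creatinine_curve")]
        for sex in SEXES
    }
    _check_empty(creat, "creatinine_curve")

    diet = [(float(a), float(v)) for a, v in _pop(raw, "diet_age_scaling", "<root>")]
    timestep = float(_pop(raw, "timestep", "<root>"))
    _check_empty(raw, "<root>")

    return TKParameters(
        absorption_gut_by_sex=gut_by_sex,
        absorption_lung=lung,
        mucociliary_to_gut=muco,
        transfer_coefficients=transfers,
        creatinine_curve=creat_curve,
        diet_age_scaling=diet,
        timestep=timestep,
    )
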