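"""Construct registry: FRET-barcode (FRETfluor) designs and their ground truth.

A FRETfluor is a short DNA duplex carrying a Cy3 donor and a Cy5 acceptor
separated by ``N`` base pairs.  Four design families tune the donor's local
physicochemical environment and therefore its donor-only lifetime and
brightness; the spacing ``N`` tunes the FRET efficiency ``E``.  The registry
holds one :class:`ConstructSpec` per design and serves as ground truth for
the photon-stream simulator and as the reference palette for classification.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ConstructFamily",
    "ConstructSpec",
    "MixtureSpec",
    "Registry",
    "RegistryError",
    "equimolar_mixture",
    "predict_fret_efficiency",
    "load_registry",
    "default_registry",
]

#: Default Forster radius, nm (representative Cy3/Cy5 literature scale).
DEFAULT_R0_NM = 5.4
#: Default helical rise per base pair, nm (B-form DNA, linear model).
DEFAULT_RISE_NM = 0.34
#: Default hydrodynamic radius of a free construct, nm.
DEFAULT_RADIUS_NM = 2.0


class RegistryError(ValueError):
    """Raised for invalid registry configuration documents."""


@dataclass(frozen=True)
class ConstructFamily:
    """Donor photophysics shared by all constructs of one design family.

    Parameters
    ----------
    name:
        Family identifier, e.g. ``"AB"`` or ``"A_cB"``.
    donor_lifetime_0:
        Donor-only fluorescence lifetime (no acceptor), ns.
    donor_brightness_0:
        Donor-only green brightness, counts ms^-1 uW^-1.
    """

    name: str
    donor_lifetime_0: float
    donor_brightness_0: float

    def __post_init__(self) -> None:
        if self.donor_lifetime_0 <= 0:
            raise RegistryError(f"family {self.name!r}: donor_lifetime_0 must be > 0")
        if self.donor_brightness_0 <= 0:
            raise RegistryError(f"family {self.name!r}: donor_brightness_0 must be > 0")


@dataclass(frozen=True)
class ConstructSpec:
    """Ground-truth photophysical description of one FRETfluor design."""

    label: str
    family: ConstructFamily
    spacing_N: int
    fret_E: float
    acceptor_brightness_scale: float = 1.0
    hydrodynamic_radius: float = DEFAULT_RADIUS_NM

    def __post_init__(self) -> None:
        if not 0.0 <= self.fret_E <= 1.0:
            raise RegistryError(f"construct {self.label!r}: E={self.fret_E} outside [0, 1]")
        if self.spacing_N < 0:
            raise RegistryError(f"construct {self.label!r}: spacing_N must be >= 0")
        if self.hydrodynamic_radius <= 0:
            raise RegistryError(f"construct {self.label!r}: hydrodynamic_radius must be > 0")

    @property
    def donor_lifetime(self) -> float:
        """Effective donor lifetime under FRET, ``tau_D0 * (1 - E)``, ns."""
        return self.family.donor_lifetime_0 * (1.0 - self.fret_E)

    @property
    def green_brightness(self) -> float:
        """Expected green brightness, counts ms^-1 uW^-1."""
        return self.family.donor_brightness_0 * (1.0 - self.fret_E)

    @property
    def red_brightness(self) -> float:
        """Expected red (acceptor) brightness, counts ms^-1 uW^-1."""
        return self.family.donor_brightness_0 * self.fret_E * self.acceptor_brightness_scale


def predict_fret_efficiency(
    spacing_N: float,
    forster_radius: float = DEFAULT_R0_NM,
    rise_per_bp: float = DEFAULT_RISE_NM,
) -> float:
    """FRET efficiency from donor-acceptor spacing under a linear-rise model.

    ``E = 1 / (1 + (N * rise / R0)^6)`` — the standard sixth-power distance
    dependence with the dye separation taken as ``N`` base pairs times the
    helical rise.  No helical-geometry correction is applied.
    """
    if forster_radius <= 0:
        raise ValueError("forster_radius must be > 0")
    if rise_per_bp <= 0:
        raise ValueError("rise_per_bp must be > 0")
    if spacing_N < 0:
        raise ValueError("spacing_N must be >= 0")
    r = spacing_N * rise_per_bp
    return 1.0 / (1.0 + (r / forster_radius) ** 6)


@dataclass
class Registry:
    """Ordered collection of :class:`ConstructSpec` with unique labels."""

    constructs: list[ConstructSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.constructs]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise RegistryError(f"duplicate construct labels: {sorted(dupes)}")
        self._by_label = {c.label: c for c in self.constructs}

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self) -> Iterator[ConstructSpec]:
        return iter(self.constructs)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> ConstructSpec:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown construct label: {label!r}") from None

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.constructs]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.constructs:
            counts[c.family.name] = counts.get(c.family.name, 0) + 1
        return counts

    def subset(self, labels: Iterable[str]) -> "Registry":
        """New registry restricted to ``labels`` (order of ``labels`` kept)."""
        return Registry([self[l] for l in labels])

    def to_config(self) -> dict:
        """Serialize back to the configuration-document schema."""
        families: list[dict] = []
        seen: set[str] = set()
        for c in self.constructs:
            if c.family.name not in seen:
                seen.add(c.family.name)
                families.append(
                    {
                        "name": c.family.name,
                        "donor_lifetime_0_ns": c.family.donor_lifetime_0,
                        "donor_brightness_0": c.family.donor_brightness_0,
                    }
                )
        constructs = [
            {
                "label": c.label,
                "family": c.family.name,
                "N": c.spacing_N,
                "E": c.fret_E,
                "acceptor_brightness_scale": c.acceptor_brightness_scale,
                "hydrodynamic_radius_nm": c.hydrodynamic_radius,
            }
            for c in self.constructs
        ]
        return {"families": families, "constructs": constructs}


@dataclass(frozen=True)
class MixtureSpec:
    """Molar composition of a measurement sample.

    Components are ``(label, concentration)`` pairs sharing one
    concentration unit; molar fractions follow from the concentrations, so
    the spec doubles as the mixture block of a simulation configuration.
    """

    components: tuple  # ((label, concentration), ...)

    def __post_init__(self) -> None:
        if not self.components:
            raise RegistryError("mixture must have at least one component")
        labels = [l for l, _ in self.components]
        if len(set(labels)) != len(labels):
            raise RegistryError("mixture labels must be unique")
        if any(c <= 0 for _, c in self.components):
            raise RegistryError("component concentrations must be > 0")

    def __len__(self) -> int:
        return len(self.components)

    @property
    def total_concentration(self) -> float:
        """Sum of component concentrations, in the components' unit."""
        return float(sum(c for _, c in self.components))

    @property
    def fractions(self) -> list[tuple]:
        """``(label, molar fraction)`` pairs; fractions sum to 1."""
        total = self.total_concentration
        return [(l, c / total) for l, c in self.components]


def equimolar_mixture(labels: Iterable[str], per_label_concentration: float) -> MixtureSpec:
    """Mixture with every label at the same concentration."""
    return MixtureSpec(tuple((l, float(per_label_concentration)) for l in labels))


def load_registry(config: Mapping | str) -> Registry:
    """Build a validated :class:`Registry` from a configuration document.

    ``config`` is either a mapping following the registry schema or a path
    to a YAML file containing one.  Constructs without an explicit ``E``
    get it from :func:`predict_fret_efficiency` using the document's
    ``fret_model`` block (defaults: R0 = 5.4 nm, rise = 0.34 nm/bp).
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise RegistryError("registry config must be a mapping")

    fret_model = config.get("fret_model") or {}
    r0 = float(fret_model.get("R0_nm", DEFAULT_R0_NM))
    rise = float(fret_model.get("rise_nm", DEFAULT_RISE_NM))

    families: dict[str, ConstructFamily] = {}
    for fam in config.get("families", []):
        f = ConstructFamily(
            name=str(fam["name"]),
            donor_lifetime_0=float(fam["donor_lifetime_0_ns"]),
            donor_brightness_0=float(fam["donor_brightness_0"]),
        )
        families[f.name] = f

    entries = config.get("constructs", [])
    if not entries:
        warnings.warn("registry config lists zero constructs", stacklevel=2)

    constructs: list[ConstructSpec] = []
    for entry in entries:
        fam_name = str(entry["family"])
        if fam_name not in families:
            raise RegistryError(
                f"construct {entry.get('label')!r}: unknown family {fam_name!r}"
            )
        n = int(entry["N"])
        e = entry.get("E")
        fret_e = float(e) if e is not None else predict_fret_efficiency(n, r0, rise)
        constructs.append(
            ConstructSpec(
                label=str(entry["label"]),
                family=families[fam_name],
                spacing_N=n,
                fret_E=fret_e,
                acceptor_brightness_scale=float(entry.get("acceptor_brightness_scale", 1.0)),
                hydrodynamic_radius=float(
                    entry.get("hydrodynamic_radius_nm", DEFAULT_RADIUS_NM)
                ),
            )
        )
    return Registry(constructs)


def default_registry() -> Registry:
    """The packaged 41-construct default registry (15 AB + 8 AB_sk + 9 A_cB + 9 AB_in)."""
    ref = importlib.resources.files("fretfluor.data") / "default_registry.yaml"
    return load_registry(yaml.safe_load(ref.read_text()))
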