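"""Mass arithmetic for stable-isotope tag screening.

Everything downstream of the instrument reduces to a handful of exact
relations between monoisotopic masses:

* the light tag adds the net composition C3H4O (one propanoylation of an
  O-H group, ~56.02621 Da); the heavy tag substitutes three 13C atoms,
  so a light/heavy isotopologue pair is split by exactly
  ``3 x (m(13C) - m(12C)) ~ 3.01006 Da`` per tag at charge 1;
* an observed m/z relates to the neutral mass through the adduct
  (H+, Na+, NH4+, or nothing for intrinsic cations such as pyridiniums),
  with the electron mass included in cationic shifts — at the ppm scale
  this 0.5 mDa matters.

All constants are pinned in ``data/constants.yaml`` shipped with the
package so computed values are bit-stable; user configs may override it
via :func:`load_constants`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import yaml

__all__ = [
    "Adduct",
    "MassConstants",
    "TagDefinition",
    "ELEMENTS",
    "PROPANOYL",
    "ADDUCTS",
    "TAGS",
    "composition_mass",
    "load_constants",
    "neutral_mass",
    "parent_mz_from_tagged",
    "ppm_error",
    "tag_delta_mz",
    "tagged_mz",
]


@dataclass(frozen=True)
class TagDefinition:
    """A light/heavy acyl tag pair.

    ``light_addition`` / ``heavy_addition`` are the net monoisotopic masses
    (Da) added to a compound by one acylation; ``pair_delta`` is their
    difference, the m/z split of a singly charged, singly tagged
    isotopologue pair.
    """

    name: str
    light_addition: float
    heavy_addition: float
    max_tags_per_compound: int = 4

    def __post_init__(self) -> None:
        if self.heavy_addition <= self.light_addition:
            raise ValueError(
                f"tag {self.name!r}: heavy_addition must exceed light_addition"
            )
        if self.max_tags_per_compound < 1:
            raise ValueError("max_tags_per_compound must be >= 1")

    @property
    def pair_delta(self) -> float:
        """heavy_addition − light_addition, exactly."""
        return self.heavy_addition - self.light_addition

    def addition(self, variant: str) -> float:
        if variant == "light":
            return self.light_addition
        if variant == "heavy":
            return self.heavy_addition
        raise ValueError(f"variant must be 'light' or 'heavy', got {variant!r}")


@dataclass(frozen=True)
class Adduct:
    """Ionizing species relating neutral (or intrinsic-cation) mass to m/z."""

    name: str
    mass_shift: float
    charge: int = 1


def composition_mass(composition: Mapping[str, int | float],
                     elements: Mapping[str, float] | None = None) -> float:
    """Monoisotopic mass of an elemental composition.

    Keys are isotope labels from the constants table (``C12``, ``H1``, ...,
    ``electron``); counts may be negative (electron loss on ionization).
    """
    table = ELEMENTS if elements is None else elements
    try:
        return sum(table[el] * n for el, n in composition.items())
    except KeyError as exc:
        raise KeyError(f"unknown element {exc.args[0]!r} in composition") from exc


@dataclass(frozen=True)
class MassConstants:
    elements: dict[str, float]
    tags: dict[str, TagDefinition]
    adducts: dict[str, Adduct]


def load_constants(path: str | None = None) -> MassConstants:
    """Load element masses, tag and adduct definitions from YAML.

    With ``path=None`` the packaged constants file is used. A user file with
    the same layout overrides everything (it is read instead, not merged).
    """
    if path is None:
        ref = importlib.resources.files("isopair").joinpath("data/constants.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    elements = {k: float(v) for k, v in raw["elements"].items()}
    tags = {}
    for name, td in raw.get("tags", {}).items():
        tags[name] = TagDefinition(
            name=name,
            light_addition=composition_mass(td["light_composition"], elements),
            heavy_addition=composition_mass(td["heavy_composition"], elements),
            max_tags_per_compound=int(td.get("max_tags_per_compound", 4)),
        )
    adducts = {
        name: Adduct(name=name, mass_shift=composition_mass(comp, elements))
        for name, comp in raw.get("adducts", {}).items()
    }
    return MassConstants(elements=elements, tags=tags, adducts=adducts)


_DEFAULTS = load_constants()
ELEMENTS: dict[str, float] = _DEFAULTS.elements
TAGS: dict[str, TagDefinition] = _DEFAULTS.tags
ADDUCTS: dict[str, Adduct] = _DEFAULTS.adducts
PROPANOYL: TagDefinition = TAGS["propanoyl"]


def tag_delta_mz(n_tags: int, charge: int = 1,
                 tag: TagDefinition = PROPANOYL) -> float:
    """m/z separation between the heavy and light ions of an n-fold tagged pair.

    Linear in ``n_tags`` and inversely proportional to ``charge``. For one
    propanoyl tag at charge 1 this is ~3.0101 m/z.
    """
    if n_tags < 0:
        raise ValueError(f"n_tags must be >= 0, got {n_tags}")
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return n_tags * tag.pair_delta / charge


def tagged_mz(parent_mz: float, n_tags: int, variant: str = "light",
              tag: TagDefinition = PROPANOYL, charge: int = 1) -> float:
    """m/z of the n-fold tagged ion given the untagged parent ion m/z."""
    if parent_mz <= 0:
        raise ValueError(f"parent_mz must be positive, got {parent_mz}")
    if n_tags < 1:
        raise ValueError(f"n_tags must be >= 1, got {n_tags}")
    if n_tags > tag.max_tags_per_compound:
        raise ValueError(
            f"n_tags={n_tags} exceeds max_tags_per_compound="
            f"{tag.max_tags_per_compound} for tag {tag.name!r}"
        )
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return parent_mz + n_tags * tag.addition(variant) / charge


def parent_mz_from_tagged(tagged: float, n_tags: int, variant: str = "light",
                          tag: TagDefinition = PROPANOYL, charge: int = 1) -> float:
    """Untagged parent ion m/z recovered from a tagged ion m/z.

    Exact inverse of :func:`tagged_mz`.
    """
    if n_tags < 1:
        raise ValueError(f"n_tags must be >= 1, got {n_tags}")
    if n_tags > tag.max_tags_per_compound:
        raise ValueError(
            f"n_tags={n_tags} exceeds max_tags_per_compound="
            f"{tag.max_tags_per_compound} for tag {tag.name!r}"
        )
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    parent = tagged - n_tags * tag.addition(variant) / charge
    if parent <= 0:
        raise ValueError(
            f"removing {n_tags} tag(s) from m/z {tagged} gives non-positive "
            f"parent m/z {parent:.4f}"
        )
    return parent


def neutral_mass(mz: float, adduct: Adduct | str) -> float:
    """Neutral (or intrinsic-cation) mass from observed m/z, charge-1 convention.

    ``adduct`` may be an :class:`Adduct` or a name from the adduct table
    ("H+", "Na+", "NH4+", "none"). With "none" the m/z is returned unchanged
    (intrinsic cations, e.g. pyridinium alkaloids).
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(
                f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
            ) from None
    if mz <= adduct.mass_shift:
        raise ValueError(
            f"m/z {mz} does not exceed the {adduct.name} adduct shift "
            f"{adduct.mass_shift:.6f}"
        )
    return mz - adduct.mass_shift


def ppm_error(observed: float, expected: float) -> float:
    """Signed relative mass error in parts per million."""
    if expected <= 0:
        raise ValueError(f"expected m/z must be positive, got {expected}")
    return 1e6 * (observed - expected) / expected
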