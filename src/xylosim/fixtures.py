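"""Bundled species parameter sets.

Four calibrated conifer parameter sets ship with the package (Pinus cembra,
Picea abies, Larix decidua — Alpine treeline — and Picea mariana, boreal
Quebec), each pairing the fixed tracheid geometry with calibrated kinetic
constants and a seasonal sugar-availability curve.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .cell import KineticParams, SpeciesParams
from .errors import UnknownSpeciesError
from .geometry import TracheidGeometryConfig
from .ring import SugarCurve

__all__ = ["FIXTURE_NAMES", "load_fixture", "list_fixtures", "species_from_dict", "species_to_dict"]

_FILES = {
    "pinus cembra": "pinus_cembra.yaml",
    "picea abies": "picea_abies.yaml",
    "larix decidua": "larix_decidua.yaml",
    "picea mariana": "picea_mariana.yaml",
}

FIXTURE_NAMES = ("Pinus cembra", "Picea abies", "Larix decidua", "Picea mariana")


def species_from_dict(d: dict) -> tuple[SpeciesParams, SugarCurve | None]:
    """Build (SpeciesParams, SugarCurve) from a parsed parameter mapping."""
    geom = TracheidGeometryConfig(**{k: float(v) for k, v in d["geometry"].items()})
    kin = KineticParams(**{k: float(v) for k, v in d["kinetics"].items()})
    sp = SpeciesParams(name=str(d.get("name", "unnamed")), geometry=geom, kinetics=kin)
    curve = None
    if "sugar_curve" in d and d["sugar_curve"] is not None:
        sc = d["sugar_curve"]
        curve = SugarCurve(family=sc["family"], a=float(sc["a"]), b=float(sc["b"]), c=float(sc["c"]))
    return sp, curve


def species_to_dict(p: SpeciesParams, curve: SugarCurve | None = None) -> dict:
    d = {
        "name": p.name,
        "geometry": {
            "CA0": p.geometry.CA0,
            "WA0": p.geometry.WA0,
            "LWA0": p.geometry.LWA0,
            "CTD": p.geometry.CTD,
            "WT0": p.geometry.WT0,
        },
        "kinetics": {k: getattr(p.kinetics, k) for k in ("vc", "CAmax", "WTstar", "vw", "WAmax", "mw", "sw", "vl", "ml", "sl")},
    }
    if curve is not None:
        d["sugar_curve"] = {"family": curve.family, "a": curve.a, "b": curve.b, "c": curve.c}
    return d


def list_fixtures() -> tuple[str, ...]:
    """Names of the bundled species parameter sets."""
    return FIXTURE_NAMES


def load_fixture(species_name: str) -> tuple[SpeciesParams, SugarCurve]:
    """Load a bundled species parameter set by (case-insensitive) name."""
    key = " ".join(species_name.strip().lower().split())
    key = key.replace("_", " ")
    if key not in _FILES:
        raise UnknownSpeciesError(
            f"unknown species {species_name!r}; bundled fixtures: {', '.join(FIXTURE_NAMES)}"
        )
    text = resources.files("xylosim.data").joinpath(_FILES[key]).read_text(encoding="utf-8")
    sp, curve = species_from_dict(yaml.safe_load(text))
    assert curve is not None
    return sp, curve
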