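"""Rule-based network-type classification.

Profiles are normalized to a designated standard (the unmodified
flour-water system): branching rate, end-point rate, protein width and
average protein length become ratios to the reference, while lacunarity
is kept absolute, because the published lacunarity bands are absolute.

Ratios are discretized into five levels (very low ... very high) by
fixed cut points, and absolute lacunarity into four bands
(low [0, 0.16], median (0.16, 0.27], high (0.27, v], very high (v, ∞)
with v = 0.55 by default).  A first-match rule table then assigns one
of five network types:

* I   — weak, fragmented network (low lacunarity, low branching,
        high end-point rate, thick threads)
* II  — strengthened homogeneous network (median lacunarity, high
        branching, low end-point rate, thin threads)
* III — contracted thick-thread network (median lacunarity)
* IV  — dense protein agglomerates (high lacunarity)
* V   — scattered agglomerates (very high lacunarity, low branching)

The rules are mutually exclusive by construction; when none matches the
call is UNCLASSIFIED with the level-step distance to the nearest rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import AttributeProfile

LEVELS = ("very_low", "low", "median", "high", "very_high")
BANDS = ("low", "median", "high", "very_high")
TYPE_LABELS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class LevelScheme:
    """Cut points mapping a ratio axis to the five qualitative levels.

    A ratio r is very_low if r <= cuts[0], low if cuts[0] < r <= cuts[1],
    median if cuts[1] < r < cuts[2], high if cuts[2] <= r < cuts[3],
    very_high if r >= cuts[3].
    """

    cuts: tuple[float, float, float, float] = (0.75, 0.92, 1.08, 1.25)

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    def level(self, ratio: float) -> str:
        c = self.cuts
        if ratio <= c[0]:
            return "very_low"
        if ratio <= c[1]:
            return "low"
        if ratio < c[2]:
            return "median"
        if ratio < c[3]:
            return "high"
        return "very_high"


@dataclass(frozen=True)
class LacunarityBands:
    """Absolute lacunarity bands: low / median / high / very_high.

    Edges default to the published 0.16 and 0.27 boundaries; the
    very-high threshold separating dense from scattered agglomerates is
    not published and defaults to 0.55, above the 2.5x-of-standard
    exemplar of the dense-agglomerate type.
    """

    edges: tuple[float, float, float] = (0.16, 0.27, 0.55)

    def __post_init__(self) -> None:
        if not (0 < self.edges[0] < self.edges[1] < self.edges[2]):
            raise ValueError("band edges must be positive and increasing")

    def band(self, lacunarity: float) -> str:
        if lacunarity < 0:
            raise ValueError("lacunarity must be >= 0")
        e = self.edges
        if lacunarity <= e[0]:
            return "low"
        if lacunarity <= e[1]:
            return "median"
        if lacunarity <= e[2]:
            return "high"
        return "very_high"


@dataclass(frozen=True)
class NormalizedProfile:
    """Attribute ratios to the reference plus absolute lacunarity."""

    branching: float
    endpoint: float
    width: float
    length: float
    lacunarity: float

    def __post_init__(self) -> None:
        for name in ("branching", "endpoint", "width", "length"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"ratio {name} must be positive and finite")
        if not (np.isfinite(self.lacunarity) and self.lacunarity >= 0):
            raise ValueError("lacunarity must be >= 0")


@dataclass(frozen=True)
class NetworkTypeCall:
    label: str                      # I..V or UNCLASSIFIED
    matched_rule: str
    levels: dict
    distance_to_nearest: float = 0.0


# rule table: band plus allowed level sets per attribute (None = unconstrained)
_RULES: list[tuple[str, str, dict[str, set[str]]]] = [
    ("I", "low", {
        "branching": {"very_low", "low"},
        "endpoint": {"high", "very_high"},
        "width": {"high", "very_high"},
    }),
    ("II", "median", {
        "branching": {"median", "high", "very_high"},
        "endpoint": {"very_low", "low", "median"},
        "width": {"very_low", "low", "median"},
    }),
    ("III", "median", {
        "branching": {"very_low", "low", "median"},
        "endpoint": {"high", "very_high"},
        "width": {"high", "very_high"},
    }),
    ("IV", "high", {
        "branching": {"very_low", "low"},
        "endpoint": {"high", "very_high"},
        "width": {"high", "very_high"},
    }),
    ("V", "very_high", {
        "branching": {"very_low", "low"},
    }),
]


def normalize_to_reference(
    profile: AttributeProfile, reference: AttributeProfile
) -> NormalizedProfile:
    """Element-wise ratios to the reference; lacunarity stays absolute."""
    pairs = {
        "branching": ("branching_rate", profile.branching_rate),
        "endpoint": ("endpoint_rate", profile.endpoint_rate),
        "width": ("protein_width_um", profile.protein_width_um),
        "length": ("avg_protein_length_um", profile.avg_protein_length_um),
    }
    ratios = {}
    for key, (attr, value) in pairs.items():
        ref = getattr(reference, attr)
        if not ref > 0:
            raise ValueError(f"reference attribute {attr} must be > 0 (got {ref})")
        ratios[key] = value / ref
    return NormalizedProfile(lacunarity=profile.lacunarity, **ratios)


def _rule_distance(
    band: str, levels: dict[str, str], rule: tuple[str, str, dict]
) -> int:
    """Level steps needed to satisfy a rule from the current levels."""
    _, rule_band, conditions = rule
    d = abs(BANDS.index(band) - BANDS.index(rule_band))
    for attr, allowed in conditions.items():
        idx = LEVELS.index(levels[attr])
        d += min(abs(idx - LEVELS.index(a)) for a in allowed)
    return d


def classify(
    normalized: NormalizedProfile,
    scheme: LevelScheme | None = None,
    bands: LacunarityBands | None = None,
) -> NetworkTypeCall:
    """Assign a network type from a normalized profile.

    Rules are evaluated in order I..V; the first (and by construction
    only) match wins.  With no match the call is UNCLASSIFIED and
    carries the minimal level-step distance to any rule.
    """
    scheme = scheme or LevelScheme()
    bands = bands or LacunarityBands()
    band = bands.band(normalized.lacunarity)
    levels = {
        "branching": scheme.level(normalized.branching),
        "endpoint": scheme.level(normalized.endpoint),
        "width": scheme.level(normalized.width),
        "length": scheme.level(normalized.length),
    }
    trace = dict(levels, band=band)
    for label, rule_band, conditions in _RULES:
        if band != rule_band:
            continue
        if all(levels[a] in allowed for a, allowed in conditions.items()):
            rule_text = f"band={rule_band} & " + " & ".join(
                f"{a} in {sorted(allowed)}" for a, allowed in conditions.items()
            )
            return NetworkTypeCall(label, rule_text, trace)
    dist = min(_rule_distance(band, levels, rule) for rule in _RULES)
    return NetworkTypeCall("UNCLASSIFIED", "", trace, distance_to_nearest=float(dist))


def classify_series(
    profiles: list[tuple[float, AttributeProfile]],
    reference: AttributeProfile,
    scheme: LevelScheme | None = None,
    bands: LacunarityBands | None = None,
) -> tuple[list[tuple[float, NetworkTypeCall]], list[tuple[float, str, str]]]:
    """Classify a dose series and report label transitions.

    ``profiles`` are (concentration, profile) pairs with concentrations
    sorted ascending.  Returns the per-concentration calls and a list of
    (concentration, from_label, to_label) transitions.
    """
    if not profiles:
        raise ValueError("empty series")
    concs = [c for c, _ in profiles]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly ascending")
    calls = [
        (c, classify(normalize_to_reference(p, reference), scheme, bands))
        for c, p in profiles
    ]
    transitions = [
        (c2, k1.label, k2.label)
        for (_, k1), (c2, k2) in zip(calls, calls[1:])
        if k1.label != k2.label
    ]
    return calls, transitions
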