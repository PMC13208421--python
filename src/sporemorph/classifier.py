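"""The quantitative microscopy identification key as a rule engine.

Traverses the published dichotomous key over collection-average spore
features exactly as printed, recording every branch taken.  The key's own
numeric gaps — average width exactly 5 µm, suprahilar depression between
2.5 and 3 % of hull area, the 12.0–12.5 µm length overlap at couplet 4 —
are preserved: inputs falling in a gap (or with conflicting categorical
characters) come back ``indeterminate`` with the candidate species of the
unresolved couplet, never a guess.  Thresholds are read from the versioned
key schema shipped with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import yaml

__all__ = [
    "MicroFeatures",
    "KeyOutcome",
    "classify_microscopy",
    "load_key_schema",
    "evaluate_macro_key",
    "SHAPES",
    "GLOEO",
]

SHAPES = ("ellipsoid_blunt", "narrowly_amygdaliform", "narrowly_subamygdaliform", "other")
GLOEO = ("sparse", "abundant", "unknown")
SPECIES = ("pulverulentus", "mediterraneensis", "poikilochromus")


@dataclass(frozen=True)
class MicroFeatures:
    """Collection-level average spore characters for the microscopy key."""

    avg_width_um: float
    avg_length_um: float
    dominant_shape: str = "other"
    depression_pct: float = 0.0
    gloeocystidia: str = "unknown"

    def __post_init__(self):
        if min(self.avg_width_um, self.avg_length_um) <= 0:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.depression_pct < 100.0):
            raise ValueError("depression_pct must lie in [0, 100)")
        if self.dominant_shape not in SHAPES:
            raise ValueError(f"dominant_shape must be one of {SHAPES}")
        if self.gloeocystidia not in GLOEO:
            raise ValueError(f"gloeocystidia must be one of {GLOEO}")


@dataclass(frozen=True)
class KeyOutcome:
    """Species label (or candidate set) plus the couplet decision path."""

    label: str  # species name or 'indeterminate'
    candidates: frozenset
    path: tuple

    def __post_init__(self):
        if not self.path:
            raise ValueError("path must be non-empty")
        if self.label != "indeterminate" and self.candidates != frozenset({self.label}):
            raise ValueError("determinate outcome must have a singleton candidate set")

    @property
    def path_string(self) -> str:
        return "→".join(self.path)


def load_key_schema(name: str = "microscopy_key.yaml") -> dict:
    with importlib.resources.files("sporemorph.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _det(label: str, path: list) -> KeyOutcome:
    return KeyOutcome(label, frozenset({label}), tuple(path))


def _indet(candidates, path: list, couplet: int) -> KeyOutcome:
    return KeyOutcome("indeterminate", frozenset(candidates), tuple(path + [f"{couplet}?"]))


def classify_microscopy(f: MicroFeatures, schema: Optional[dict] = None) -> KeyOutcome:
    """Run the microscopy key on one set of collection-average features.

    Deterministic; unknown or conflicting characters route to indeterminate.
    The path records couplet ids with the branch taken ('1a', '4b', ...;
    '5?' marks the couplet at which resolution failed).
    """
    thr = (schema or load_key_schema())["thresholds"]
    w_split = thr["width_split_um"]
    l_long = thr["length_long_um"]
    l_min = thr["length_min_um"]
    d_hi = thr["depression_pronounced_pct"]
    d_lo = thr["depression_shallow_pct"]

    path: list = []
    # couplet 1: average spore width
    if f.avg_width_um < w_split:
        path.append("1a")
    elif f.avg_width_um > w_split:
        path.append("1b")
    else:  # exactly on the split: the key does not assign it
        return _indet(SPECIES, path, 1)

    if path[-1] == "1a":
        # couplet 2: average spore length
        if f.avg_length_um > l_long:
            path.append("2a")
            return _det("pulverulentus", path)
        if f.avg_length_um < l_long:
            path.append("2b")
        else:
            return _indet({"pulverulentus", "poikilochromus"}, path, 2)
        # couplet 3: shape + depression + gloeocystidia
        if f.dominant_shape == "ellipsoid_blunt" and f.gloeocystidia == "abundant":
            path.append("3a")
            return _det("poikilochromus", path)
        if (
            f.dominant_shape == "narrowly_amygdaliform"
            and f.depression_pct > d_hi
            and f.gloeocystidia == "sparse"
        ):
            path.append("3b")
            return _det("pulverulentus", path)
        return _indet({"pulverulentus", "poikilochromus"}, path, 3)

    # couplet 4: categorical characters first, dimensions second
    if (
        f.dominant_shape == "ellipsoid_blunt"
        and f.gloeocystidia == "abundant"
        and f.avg_length_um < l_long
    ):
        path.append("4a")
        return _det("poikilochromus", path)
    if (
        f.dominant_shape in ("narrowly_subamygdaliform", "narrowly_amygdaliform")
        and f.gloeocystidia == "sparse"
        and f.avg_length_um > l_min
    ):
        path.append("4b")
    else:
        return _indet(SPECIES, path, 4)

    # couplet 5: depression regime, with the printed (2.5, 3]% gap preserved
    if f.depression_pct > d_hi:
        path.append("5a")
        return _det("pulverulentus", path)
    if f.depression_pct < d_lo:
        path.append("5b")
        return _det("mediterraneensis", path)
    return _indet({"pulverulentus", "mediterraneensis"}, path, 5)


def evaluate_macro_key(answers: dict, schema: Optional[dict] = None) -> KeyOutcome:
    """Best-effort traversal of the macromorphological key (experimental).

    ``answers`` maps "<couplet><branch>" (e.g. "1a") to True/False.  The
    first affirmed branch of each couplet is followed; a couplet with no
    affirmed branch halts with all downstream species as candidates.
    """
    schema = schema or load_key_schema("macro_key.yaml")
    couplets = schema["couplets"]
    path: list = []
    current = 1
    while True:
        branches = couplets[current]
        taken = None
        for branch, node in branches.items():
            if answers.get(f"{current}{branch}"):
                taken = (branch, node)
                break
        if taken is None:
            labels = _reachable_labels(couplets, current)
            return _indet(labels, path, current)
        branch, node = taken
        path.append(f"{current}{branch}")
        if "label" in node:
            return _det(node["label"], path)
        current = node["goto"]


def _reachable_labels(couplets: dict, start: int) -> set:
    out: set = set()
    stack = [start]
    while stack:
        c = stack.pop()
        for node in couplets[c].values():
            if "label" in node:
                out.add(node["label"])
            else:
                stack.append(node["goto"])
    return out
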