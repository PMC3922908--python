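"""Model specification for the second-order Health Belief Model CFA.

The measurement instrument is a 22-item Likert questionnaire with five
subscales, one per HBM construct:

* SUS — perceived susceptibility (items 1-5)
* SER — perceived seriousness (items 6-9)
* BEN — perceived benefits of taking action (items 10-14)
* BAR — barriers to taking action (items 15-18)
* CTA — cues to action (items 19-22)

A single second-order "health belief" factor drives the five first-order
constructs; in addition a directed structural path BAR -> CTA allows
perceived barriers to influence attention to cues.  Each item loads on
exactly one construct (simple structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FACTORS: tuple[str, ...] = ("SUS", "SER", "BEN", "BAR", "CTA")

#: item -> construct assignment for the 22-item instrument, in item order.
DEFAULT_ITEM_FACTOR_MAP: tuple[str, ...] = (
    ("SUS",) * 5 + ("SER",) * 4 + ("BEN",) * 5 + ("BAR",) * 4 + ("CTA",) * 4
)

ITEM_COLUMNS: tuple[str, ...] = tuple(f"item_{i:02d}" for i in range(1, 23))
METADATA_COLUMNS: tuple[str, ...] = ("respondent_id", "cohort", "age", "gender")


class ModelSpecError(ValueError):
    """Raised when a factor-model specification is internally inconsistent."""


@dataclass(frozen=True)
class HBMModelSpec:
    """Structure of the second-order HBM confirmatory factor model.

    Parameters
    ----------
    item_factor_map
        For each item (in instrument order) the name of the first-order
        factor it loads on.
    factors
        First-order factor names, in the order used for all matrices.
    second_order_factor
        Name of the second-order factor; its variance is fixed to 1 for
        identification.
    structural_paths
        Directed (source, destination) pairs among first-order factors.
        Must be acyclic.
    markers
        Per-factor index (into the item list) of the marker item whose
        unstandardized loading is fixed to 1.  Defaults to the first item
        of each factor.
    """

    item_factor_map: tuple[str, ...] = DEFAULT_ITEM_FACTOR_MAP
    factors: tuple[str, ...] = FACTORS
    second_order_factor: str = "health_belief"
    structural_paths: tuple[tuple[str, str], ...] = (("BAR", "CTA"),)
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.item_factor_map) - set(self.factors)
        if unknown:
            raise ModelSpecError(f"items mapped to unknown factors: {sorted(unknown)}")
        counts = {f: self.item_factor_map.count(f) for f in self.factors}
        thin = [f for f, c in counts.items() if c < 2]
        if thin:
            raise ModelSpecError(f"factors with fewer than 2 items: {thin}")
        for src, dst in self.structural_paths:
            if src not in self.factors or dst not in self.factors:
                raise ModelSpecError(f"structural path ({src}, {dst}) uses unknown factor")
        self._check_acyclic()
        if not self.markers:
            # default marker: first item of each factor
            auto = {}
            for f in self.factors:
                auto[f] = self.item_factor_map.index(f)
            object.__setattr__(self, "markers", auto)
        for f in self.factors:
            i = self.markers.get(f)
            if i is None or self.item_factor_map[i] != f:
                raise ModelSpecError(f"marker for factor {f} is missing or mismapped")

    def _check_acyclic(self) -> None:
        children: dict[str, list[str]] = {f: [] for f in self.factors}
        for src, dst in self.structural_paths:
            children[src].append(dst)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ModelSpecError("structural paths contain a cycle")
            if state.get(node) == 2:
                return
            state[node] = 1
            for c in children[node]:
                visit(c)
            state[node] = 2

        for f in self.factors:
            visit(f)

    # -- derived structure -------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.item_factor_map)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def factor_index(self, name: str) -> int:
        return self.factors.index(name)

    @property
    def item_factor_indices(self) -> np.ndarray:
        """Integer factor index of each item, shape ``(n_items,)``."""
        lut = {f: k for k, f in enumerate(self.factors)}
        return np.array([lut[f] for f in self.item_factor_map], dtype=int)

    def items_of(self, factor: str) -> list[int]:
        """0-based item indices loading on ``factor``."""
        return [i for i, f in enumerate(self.item_factor_map) if f == factor]

    def structural_matrix(self, coefficients: np.ndarray) -> np.ndarray:
        """Assemble the (n_factors, n_factors) matrix B from path coefficients.

        ``B[dst, src]`` holds the coefficient of the path src -> dst.
        """
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (len(self.structural_paths),):
            raise ModelSpecError("one coefficient per structural path required")
        B = np.zeros((self.n_factors, self.n_factors))
        for c, (src, dst) in zip(coefficients, self.structural_paths):
            B[self.factor_index(dst), self.factor_index(src)] = c
        return B

    @property
    def free_loading_items(self) -> list[int]:
        """Items whose loading is a free parameter (all non-markers)."""
        fixed = set(self.markers.values())
        return [i for i in range(self.n_items) if i not in fixed]


DEFAULT_SPEC = HBMModelSpec()

#: Reference standardized solution for the 22-item instrument: second-order
#: coefficients (HB -> SUS, SER, BEN, BAR, CTA), the BAR -> CTA structural
#: coefficient, and the per-item total effects of health belief.  These are
#: the canonical generating values used by the simulation benchmarks.
REFERENCE_GAMMA: tuple[float, ...] = (0.72, 0.84, 0.87, -0.18, 0.60)
REFERENCE_BETA: float = 0.35
REFERENCE_TOTAL_EFFECTS: tuple[float, ...] = (
    0.57, 0.57, 0.66, 0.66, 0.63,           # SUS
    0.73, 0.74, 0.71, 0.61,                 # SER
    0.72, 0.78, 0.74, 0.79, 0.75,           # BEN
    -0.14, -0.14, -0.16, -0.16,             # BAR
    0.48, 0.50, 0.53, 0.54,                 # CTA
)
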