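"""Likert rescaling and composite conspiracism scoring.

Conspiracism is measured by self-report instruments with different response
ranges (e.g., an 11-item mentality scale on 1–7 and a 15-item generic-beliefs
scale on 1–5). To pool them, every response is rescaled to a common 0–1
range with z = (x − min(L)) / (max(L) − min(L)), so 0 is strong
disagreement, 1 strong agreement, and the midpoint of an odd scale lands at
exactly .50. A participant's composite score is the mean of their rescaled
items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


@dataclass(frozen=True)
class ScaleSpec:
    name: str
    n_items: int
    likert_min: int
    likert_max: int
    reverse_items: frozenset[int] = frozenset()
    #: optional named item subsets (e.g., skepticism / ideation facets)
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be < likert_max")
        items = set(range(1, self.n_items + 1))
        if not set(self.reverse_items) <= items:
            raise ValueError("reverse_items outside item range")
        for sub, members in self.subscales.items():
            if not set(members) <= items:
                raise ValueError(f"subscale {sub!r} references unknown items")


def rescale_likert(
    x: int,
    spec: ScaleSpec,
    item: int | None = None,
    pid: str | None = None,
) -> float:
    """Rescale one Likert response to [0, 1]; reverse-keyed items flip to 1 − z."""
    if not spec.likert_min <= x <= spec.likert_max:
        raise ValueError(
            f"response {x} outside [{spec.likert_min}, {spec.likert_max}] "
            f"on scale {spec.name!r} (pid={pid!r}, item={item!r})"
        )
    z = (x - spec.likert_min) / (spec.likert_max - spec.likert_min)
    if item is not None and item in spec.reverse_items:
        z = 1.0 - z
    return z


def composite_conspiracism(
    responses: Mapping[int, int | None],
    spec: ScaleSpec,
    strict: bool = False,
) -> float:
    """Mean of the rescaled item responses; the participant's trait score.

    Missing items (None) are excluded under the default available-item-mean
    policy; in ``strict`` mode any missing item raises. All items missing
    yields NaN.
    """
    values = []
    n_missing = 0
    for item in range(1, spec.n_items + 1):
        x = responses.get(item)
        if x is None:
            n_missing += 1
            if strict:
                raise ValueError(f"missing item {item} on scale {spec.name!r} (strict mode)")
            continue
        values.append(rescale_likert(x, spec, item=item))
    if not values:
        return float("nan")
    return float(np.mean(values))


def subscale_score(
    responses: Mapping[int, int | None],
    spec: ScaleSpec,
    subscale: str,
) -> float:
    """Available-item mean of the rescaled responses of one named subscale."""
    members = spec.subscales.get(subscale)
    if members is None:
        raise KeyError(f"scale {spec.name!r} has no subscale {subscale!r}")
    values = [
        rescale_likert(responses[i], spec, item=i)
        for i in members
        if responses.get(i) is not None
    ]
    return float(np.mean(values)) if values else float("nan")
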