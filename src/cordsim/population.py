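"""Logistic tumour-cell population dynamics with trigger-dependent growth.

Cell density follows a logistic law: linear net growth ``(a1 - a2)*c`` minus
quadratic saturation ``b*c^2``.  While the apoptosis trigger is off the
positive steady state (the carrying capacity, = 1 in the dimensionless
density scale) is globally attracting.  When the trigger fires, the growth
rate collapses to ``a1_triggered < a2`` and extinction (c = 0) becomes the
only attractor.  An equivalent variant adds an extra linear death rate
instead of reducing growth; both give the same qualitative outcome and the
variant is selectable via ``mode_semantics``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .parameters import DimensionlessModel

__all__ = ["PopulationState", "population_rate", "EXTINCTION_FLOOR"]

GrowthMode = Literal["normal", "triggered"]

#: dimensionless density below which a node is reported dead in summaries;
#: the dynamics themselves never clip at this value.
EXTINCTION_FLOOR = 1e-6


@dataclass(frozen=True)
class PopulationState:
    """Per-node cell density and growth mode."""

    c_t: np.ndarray
    growth_mode: np.ndarray     # boolean, True = triggered


def growth_coefficients(
    m: DimensionlessModel,
    triggered,
    variant: Literal["reduced_growth", "extra_death"] = "reduced_growth",
    extra_death_rate: float | None = None,
):
    """Per-node net linear growth coefficient (per t_scale).

    ``reduced_growth`` swaps a1 for a1_triggered on triggered nodes (the
    default semantics); ``extra_death`` keeps a1 and adds a linear death term
    chosen so the triggered net rate matches ``growth_net_triggered`` unless
    a custom ``extra_death_rate`` (per t_scale) is given.
    """
    triggered = np.asarray(triggered, dtype=bool)
    if variant == "reduced_growth":
        a_trig = m.growth_net_triggered
    elif variant == "extra_death":
        extra = (m.growth_net - m.growth_net_triggered
                 if extra_death_rate is None else extra_death_rate)
        a_trig = m.growth_net - extra
    else:
        raise ValueError(f"unknown growth-collapse variant {variant!r}")
    return np.where(triggered, a_trig, m.growth_net)


def population_rate(
    c_t,
    growth_mode,
    m: DimensionlessModel,
    variant: Literal["reduced_growth", "extra_death"] = "reduced_growth",
):
    """Dimensionless dc/dt: ``a_eff*c - b*c^2`` with mode-dependent ``a_eff``."""
    c_t = np.asarray(c_t, dtype=float)
    if np.any(c_t < -1e-12):
        raise ValueError("cell density must be non-negative")
    a = growth_coefficients(m, growth_mode, variant)
    out = a * c_t - m.logistic_b * c_t * c_t
    return out if out.ndim else float(out)
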