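"""Synthetic branch-event tables with known initiation and loss rates.

Branch initiations per neuron are Poisson with the specified per-hour
rate for each branch type — GCB (growth cone bifurcation: splitting of
the growing tip) and IB (interstitial back-branching from the shaft).
Whether an initiated branch later retracts is Bernoulli with the
type-specific loss probability; retracted branches carry an
anterior/posterior direction label drawn with the specified anterior
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError

EVENT_COLUMNS = [
    "neuron_id", "embryo_id", "type", "t_init_min",
    "retracted", "t_retract_min", "direction",
]


@dataclass
class SynthEventTableSpec:
    n_neurons: int = 10
    duration_h: float = 2.0
    gcb_rate_per_h: float = 2.22
    ib_rate_per_h: float = 0.99
    gcb_loss_prob: float = 0.13
    ib_loss_prob: float = 0.10
    anterior_fraction_of_lost: float = 0.5
    neurons_per_embryo: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("gcb_loss_prob", "ib_loss_prob", "anterior_fraction_of_lost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.gcb_rate_per_h < 0 or self.ib_rate_per_h < 0:
            raise ConfigError("rates must be non-negative")
        if self.duration_h <= 0 or self.n_neurons < 1:
            raise ConfigError("duration_h must be positive and n_neurons >= 1")


def generate_event_table(spec: SynthEventTableSpec) -> pd.DataFrame:
    """Simulate a BranchEvent table (columns as in EVENT_COLUMNS)."""
    rng = np.random.default_rng(spec.seed)
    dur_min = spec.duration_h * 60.0
    rows = []
    for n in range(spec.n_neurons):
        embryo = n // spec.neurons_per_embryo
        for btype, rate, loss in (
            ("GCB", spec.gcb_rate_per_h, spec.gcb_loss_prob),
            ("IB", spec.ib_rate_per_h, spec.ib_loss_prob),
        ):
            k = rng.poisson(rate * spec.duration_h)
            t_init = np.sort(rng.uniform(0.0, dur_min, size=k))
            retracted = rng.random(k) < loss
            for t0, r in zip(t_init, retracted):
                t_r = rng.uniform(t0, dur_min) if r else np.nan
                direction = (
                    ("anterior" if rng.random() < spec.anterior_fraction_of_lost
                     else "posterior") if r else None
                )
                rows.append(
                    dict(neuron_id=n, embryo_id=embryo, type=btype,
                         t_init_min=float(t0), retracted=bool(r),
                         t_retract_min=float(t_r) if r else np.nan,
                         direction=direction)
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
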