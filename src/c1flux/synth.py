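"""Synthetic test inputs with ground truth known by construction.

Two generators live here:

* :func:`make_known_optimum_network` builds a small flux-consistent network
  whose LP optimum is *provably* the substrate bound: a linear production
  chain with unit stoichiometry whose interior capacities all exceed the
  substrate bound, decorated with decoy branches that certifiably cannot
  carry improving flux (they either end in a dead-end metabolite, which
  forces zero flux at steady state, or are bounded to zero).
* :func:`make_trace` builds a plate-reader absorbance trace with a known
  underlying enzymatic rate and optional Gaussian noise.

Both are deterministic functions of their seed (one local generator per
call, never process-global state).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Tuple

import numpy as np

from .assay import AssayTrace
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticTraceSpec",
    "make_known_optimum_network",
    "make_trace",
    "make_standard_curve_points",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    seed: int
    n_chain: int = 4  # metabolites along the production path
    n_branch: int = 2  # decoy branches
    bound_scale: float = 1.0  # substrate bound = the known optimum

    def __post_init__(self):
        if self.n_chain < 2:
            raise ValueError("n_chain must be >= 2")
        if self.n_branch < 0:
            raise ValueError("n_branch must be >= 0")
        if self.bound_scale <= 0:
            raise ValueError("bound_scale must be positive")


@dataclass(frozen=True)
class SyntheticTraceSpec:
    seed: int
    true_rate: float = 0.01  # mM/min
    curve_slope: float = 0.62  # AU/mM
    noise_sd: float = 0.001  # AU
    n_points: int = 10
    dt: float = 1.0  # minutes between reads
    intercept: float = 0.05  # AU at t=0

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_known_optimum_network(
    spec: SyntheticNetworkSpec,
) -> Tuple[MetabolicNetwork, float]:
    """Build a network whose maximum sink flux equals ``bound_scale``.

    The chain M0 -> M1 -> ... -> M_last has unit stoichiometry; every
    interior capacity and the sink bound are drawn above the substrate
    exchange bound, so the substrate bound is the unique binding constraint
    and the optimum is ``bound_scale`` by construction.  All metabolites in
    one network share a carbon count, so every internal reaction (decoys
    included) is carbon-balanced.
    """
    rng = np.random.default_rng(spec.seed)
    carbon = int(rng.integers(1, 7))
    b = spec.bound_scale

    mets: List[Metabolite] = [
        Metabolite(f"M{i}", f"chain metabolite {i}", carbon)
        for i in range(spec.n_chain)
    ]
    reactions: List[Reaction] = [
        Reaction("EX_in", {"M0": Fraction(1)}, name="substrate import",
                 lower_bound=0.0, upper_bound=b, kind="exchange")
    ]
    for i in range(spec.n_chain - 1):
        cap = b * float(rng.uniform(1.5, 3.0))
        reactions.append(
            Reaction(f"R{i}", {f"M{i}": Fraction(-1), f"M{i + 1}": Fraction(1)},
                     name=f"chain step {i}", lower_bound=0.0, upper_bound=cap)
        )
    sink_cap = b * float(rng.uniform(1.5, 3.0))
    reactions.append(
        Reaction("SINK_out", {f"M{spec.n_chain - 1}": Fraction(-1)},
                 name="product sink", lower_bound=0.0, upper_bound=sink_cap,
                 kind="sink")
    )

    for k in range(spec.n_branch):
        src = int(rng.integers(0, spec.n_chain))
        mets.append(Metabolite(f"D{k}", f"decoy metabolite {k}", carbon))
        zero_bounded = bool(rng.integers(0, 2))
        cap = 0.0 if zero_bounded else b * float(rng.uniform(0.5, 2.0))
        # D{k} has no consumer: steady state forces zero flux even when the
        # bound is open, so the decoy is certifiably non-improving.
        reactions.append(
            Reaction(f"DEC{k}", {f"M{src}": Fraction(-1), f"D{k}": Fraction(1)},
                     name=f"decoy branch {k}", lower_bound=0.0, upper_bound=cap)
        )

    return MetabolicNetwork(mets, reactions), b


def make_trace(spec: SyntheticTraceSpec) -> Tuple[AssayTrace, float]:
    """Absorbance trace A(t) = intercept + slope*rate*t + N(0, noise_sd).

    Returns the trace and the ground-truth rate (mM/min).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.dt
    clean = spec.intercept + spec.curve_slope * spec.true_rate * t
    noise = rng.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd > 0 else 0.0
    return (
        AssayTrace(times=tuple(t.tolist()),
                   absorbances=tuple((clean + noise).tolist()),
                   replicate_id=f"synth-{spec.seed}"),
        spec.true_rate,
    )


def make_standard_curve_points(
    seed: int,
    slope: float = 0.62,
    intercept: float = 0.0,
    noise_sd: float = 0.002,
    concentrations: Tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> Tuple[np.ndarray, np.ndarray]:
    """Calibration points (conc mM, absorbance AU) for a known linear curve."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    ab = intercept + slope * conc + rng.normal(0.0, noise_sd, conc.size)
    return conc, ab
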