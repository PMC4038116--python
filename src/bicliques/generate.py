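"""Random bipartite graph generators.

Two models: the classic Erdős–Rényi model with a uniform edge probability
``p``, and a degree-controlled model in which each smaller-partition vertex
receives a target degree drawn from a distribution with prescribed mean μ
and coefficient of variation CV = σ/μ, then picks that many distinct
neighbors uniformly from the larger partition.

The degree distribution for the CV model is a gamma with shape 1/CV² and
scale μ·CV² (mean μ, standard deviation μ·CV before rounding), rounded to
the nearest integer and clipped to [1, m]; CV = 0 degenerates to the
constant round(μ).  The gamma is non-negative and matches mean and CV
exactly with two parameters, which is all the model prescribes.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
parameters and seed always produce the identical edge set.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .graph_core import BipartiteGraph


def _labels(prefix: str, count: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(count))


def er_bipartite(m: int, n: int, p: float, seed: int) -> BipartiteGraph:
    """Erdős–Rényi bipartite graph: each of the m·n possible edges is
    included independently with probability ``p``.

    Left labels are ``u1..um`` (the larger partition by convention),
    right labels ``v1..vn``.
    """
    if m < 0 or n < 0:
        raise InputError("partition sizes must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"edge probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    B = rng.random((m, n)) < p
    return BipartiteGraph.from_biadjacency(_labels("u", m), _labels("v", n), B)


def cv_bipartite(m: int, n: int, mu: float, cv: float, seed: int) -> BipartiteGraph:
    """Degree-controlled bipartite graph.

    Each right vertex draws a target degree (mean ``mu``, coefficient of
    variation ``cv``), clipped to [1, m], and connects to that many
    distinct left vertices chosen uniformly without replacement.
    """
    if m <= 0 or n < 0:
        raise InputError("partition sizes must be positive / non-negative")
    if mu < 0 or cv < 0:
        raise InputError("mu and cv must be non-negative")
    if mu > m:
        raise InputError(f"mean degree {mu} exceeds larger partition size {m}")
    if round(mu) < 1:
        raise InputError("round(mu) must be at least 1")
    rng = np.random.default_rng(seed)
    if cv == 0:
        degrees = np.full(n, round(mu), dtype=int)
    else:
        shape = 1.0 / cv**2
        scale = mu * cv**2
        degrees = np.rint(rng.gamma(shape, scale, size=n)).astype(int)
    degrees = np.clip(degrees, 1, m)
    B = np.zeros((m, n), dtype=bool)
    for j in range(n):
        B[rng.choice(m, size=degrees[j], replace=False), j] = True
    return BipartiteGraph.from_biadjacency(_labels("u", m), _labels("v", n), B)
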