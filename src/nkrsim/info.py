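"""Information-theoretic analysis of dose-conditional pVav1 responses.

The ligand dose (NKG2DL copy number) is the channel input ``s``; the
total pVav1 copy number at a chosen read-out time is the output ``o``.
Replicate ensembles give the conditional distribution P(o|s); mutual
information (in bits) under a uniform input prior quantifies how many
dose levels the read-out can separate, and Blahut--Arimoto iteration
maximizes MI over the input distribution to give the channel capacity
together with the capacity-achieving (typically bimodal) input weights.

Response distributions can also be summarized by maximum-likelihood
Gamma fits, compared across doses through the closed-form Gamma--Gamma
Kullback--Leibler divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, gammaln

LN2 = np.log(2.0)


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood Gamma(shape, scale) fit of a response sample."""

    shape: float
    scale: float
    offset: float = 0.0      # pseudo-offset added when zeros are present
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Gamma parameters must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def fit_gamma(samples, offset_if_zero: float = 0.5) -> GammaFit:
    """ML Gamma fit of non-negative response samples.

    The Gamma support excludes 0, so when zero counts occur every sample
    is shifted by ``offset_if_zero`` (recorded in the fit) before
    fitting with the location pinned at zero.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a Gamma fit")
    if np.any(x < 0):
        raise ValueError("samples must be non-negative")
    if np.var(x) == 0:
        raise ValueError("degenerate (constant) samples")
    off = offset_if_zero if np.any(x == 0) else 0.0
    shape, _, scale = stats.gamma.fit(x + off, floc=0)
    return GammaFit(shape=float(shape), scale=float(scale), offset=off,
                    n=int(x.size))


def kl_gamma(p: GammaFit, q: GammaFit, bits: bool = True) -> float:
    """Closed-form KL divergence KL(p || q) between two Gamma fits.

    In nats:  (a_p - a_q) psi(a_p) - ln G(a_p) + ln G(a_q)
              + a_q ln(s_q / s_p) + a_p (s_p - s_q) / s_q
    Returned in bits by default.
    """
    ap, sp = p.shape, p.scale
    aq, sq = q.shape, q.scale
    kl = ((ap - aq) * digamma(ap) - gammaln(ap) + gammaln(aq)
          + aq * np.log(sq / sp) + ap * (sp - sq) / sq)
    kl = float(max(kl, 0.0))
    return kl / LN2 if bits else kl


@dataclass
class Channel:
    """Discrete memoryless channel: doses in, pVav1 count bins out."""

    inputs: np.ndarray           # (n_s,) dose values
    outputs: np.ndarray          # (n_o,) bin centers
    cond: np.ndarray             # (n_s, n_o) rows P(o|s)
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond, dtype=float)
        if self.cond.ndim != 2 or self.cond.shape[0] != len(self.inputs):
            raise ValueError("conditional matrix shape mismatch")
        if np.any(self.cond < 0) or \
           not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each row of P(o|s) must be a distribution")
        if self.prior is None:
            self.prior = np.full(len(self.inputs), 1.0 / len(self.inputs))
        self.prior = np.asarray(self.prior, dtype=float)
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("input prior must sum to 1")


def entropy_bits(p) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(channel: Channel, prior=None) -> float:
    """Plug-in mutual information in bits for a fixed input prior
    (uniform by default).  Equals H(s) - H(s|o)."""
    q = np.asarray(prior, dtype=float) if prior is not None else channel.prior
    joint = q[:, None] * channel.cond          # P(o, s)
    r = joint.sum(axis=0)                      # R(o)
    mask = joint > 0
    ratio = joint[mask] / (q[:, None] * r[None, :])[mask]
    return float((joint[mask] * np.log2(ratio)).sum())


@dataclass
class InfoResult:
    mi_uniform: float            # MI at the uniform prior, bits
    cc: float                    # channel capacity, bits
    q_star: np.ndarray           # capacity-achieving input distribution
    iterations: int
    gap: float                   # residual capacity gap bound, bits
    objective_trace: np.ndarray  # lower bound per iteration (non-decreasing)


def blahut_arimoto(cond, tol: float = 1e-9, max_iter: int = 50000) -> InfoResult:
    """Channel capacity by Blahut--Arimoto alternating maximization.

    Iterates the input distribution Q; convergence is declared when the
    standard capacity gap bound max_s D(P(.|s) || R) - I(Q) drops below
    ``tol`` (bits).  The lower-bound objective is non-decreasing.
    """
    P = np.asarray(cond, dtype=float)
    if P.ndim != 2 or np.any(P < 0) or \
       not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("conditional matrix rows must be distributions")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_s = P.shape[0]
    Q = np.full(n_s, 1.0 / n_s)
    logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), 0.0)
    trace = []
    for it in range(1, max_iter + 1):
        R = Q @ P                                   # output marginal
        with np.errstate(divide="ignore"):
            logR = np.log(np.maximum(R, 1e-300))
        D = np.where(P > 0, P * (logP - logR[None, :]), 0.0).sum(axis=1)
        lower = float(Q @ D) / LN2                  # = MI(Q), bits
        upper = float(D.max()) / LN2
        trace.append(lower)
        if upper - lower < tol:
            break
        Q = Q * np.exp(D - D.max())
        Q /= Q.sum()
    else:
        raise RuntimeError(
            f"Blahut-Arimoto did not converge: gap {upper - lower:.3g} bits")
    uniform = np.full(n_s, 1.0 / n_s)
    chan = Channel(inputs=np.arange(n_s), outputs=np.arange(P.shape[1]),
                   cond=P, prior=uniform)
    return InfoResult(mi_uniform=mutual_information(chan), cc=lower,
                      q_star=Q, iterations=it, gap=upper - lower,
                      objective_trace=np.array(trace))


def build_channel(responses: dict[int, np.ndarray], method: str = "hist",
                  bin_width: float = 1.0, min_samples: int = 20) -> Channel:
    """Estimate the dose -> pVav1 channel from replicate ensembles.

    ``responses`` maps each dose to its sample of pVav1 counts at the
    read-out time.  ``method='hist'`` uses the empirical histogram on
    integer count bins (width 1 molecule by default); ``method='gamma'``
    smooths each row with its ML Gamma fit evaluated on the same bins,
    which stabilizes the estimate at modest replicate numbers.
    """
    if len(responses) < 2:
        raise ValueError("need at least two doses")
    doses = np.array(sorted(responses), dtype=int)
    samples = [np.asarray(responses[d], dtype=float) for d in doses]
    for d, x in zip(doses, samples):
        if x.size < min_samples:
            raise ValueError(f"dose {d}: {x.size} < {min_samples} replicates")
        if x.size == 0:
            raise ValueError(f"empty ensemble for dose {d}")
    hi = max(x.max() for x in samples)
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cond = np.zeros((len(doses), len(centers)))
    for i, x in enumerate(samples):
        if method == "hist":
            h, _ = np.histogram(x, bins=edges)
            cond[i] = h / h.sum()
        elif method == "gamma":
            if np.var(x) == 0 or x.size < 10:
                # degenerate or too small for a stable ML fit:
                # fall back to the empirical histogram
                h, _ = np.histogram(x, bins=edges)
                cond[i] = h / h.sum()
            else:
                fit = fit_gamma(x)
                cdf = stats.gamma.cdf(edges + fit.offset, fit.shape,
                                      scale=fit.scale)
                row = np.diff(cdf)
                # fold the open tail into the last bin
                row[-1] += 1.0 - cdf[-1]
                cond[i] = row / row.sum()
        else:
            raise ValueError(f"unknown method {method!r}")
    return Channel(inputs=doses, outputs=centers, cond=cond)


def bootstrap_mi_se(responses: dict[int, np.ndarray], n_boot: int = 200,
                    method: str = "hist", rng=None,
                    min_samples: int = 20) -> float:
    """Bootstrap standard error of the uniform-prior MI estimate."""
    rng = np.random.default_rng(rng)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        res = {d: rng.choice(x, size=len(x), replace=True)
               for d, x in responses.items()}
        vals[b] = mutual_information(
            build_channel(res, method=method, min_samples=min_samples))
    return float(vals.std(ddof=1))
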