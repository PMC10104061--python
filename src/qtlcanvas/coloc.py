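"""Signal-level colocalisation from per-variant log Bayes factors.

Given two fine-mapped signals (e.g. a GWAS signal and a molecular-QTL
signal) each summarised by a vector of natural-log Bayes factors over
variants, the engine evaluates the posterior of the five standard
hypotheses on the shared-variant grid of size Q:

  H0 neither trait associated; H1/H2 only the first/second associated;
  H3 both associated, distinct causal variants; H4 a shared causal variant.

With lse = log-sum-exp over the Q aligned LBFs l1, l2 and priors p1, p2,
p12 per configuration:

  S0 = 0
  S1 = lse(l1) + log p1
  S2 = lse(l2) + log p2
  S4 = lse(l1 + l2) + log p12
  S3 = log( exp(lse(l1) + lse(l2)) - exp(lse(l1 + l2)) ) + log(p1 * p2)

and PPk = softmax(S0..S4). The S3 difference is evaluated in log space; in
the degenerate case where the cross term equals (or numerically exceeds)
the product term — e.g. Q = 1 — S3 is -inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

logger = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 5e-6

MIN_SHARED_WARN = 10
S3_GUARD_TOL = 1e-12


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class SignalLBF:
    """One fine-mapped signal: variant IDs and aligned natural-log BFs."""

    signal_id: str
    variant_ids: tuple[str, ...]
    lbf: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.lbf, dtype=float)
        object.__setattr__(self, "lbf", arr)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        if len(self.variant_ids) != arr.size:
            raise ColocError(
                f"{self.signal_id}: {len(self.variant_ids)} variants vs "
                f"{arr.size} LBF values"
            )
        if not np.all(np.isfinite(arr)):
            raise ColocError(f"{self.signal_id}: non-finite LBF values")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ColocError(f"{self.signal_id}: duplicate variant IDs")


@dataclass(frozen=True)
class ColocResult:
    """PP0-PP4 for one signal pair, plus priors and overlap bookkeeping."""

    signal_a: str
    signal_b: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_shared_variants: int
    p1: float
    p2: float
    p12: float
    low_overlap: bool = False

    def __post_init__(self) -> None:
        pps = self.pps
        if any(not (0 <= p <= 1) for p in pps):
            raise ColocError("posterior outside [0, 1]")
        if abs(sum(pps) - 1) > 1e-9:
            raise ColocError(f"posteriors sum to {sum(pps)}, not 1")

    @property
    def pps(self) -> tuple[float, float, float, float, float]:
        return (self.pp0, self.pp1, self.pp2, self.pp3, self.pp4)


def _align(a: SignalLBF, b: SignalLBF) -> tuple[np.ndarray, np.ndarray, int]:
    idx_b = {v: i for i, v in enumerate(b.variant_ids)}
    pairs = [(i, idx_b[v]) for i, v in enumerate(a.variant_ids) if v in idx_b]
    if not pairs:
        raise ColocError(
            f"no shared variants between {a.signal_id} and {b.signal_id}"
        )
    ia, ib = zip(*pairs)
    return a.lbf[list(ia)], b.lbf[list(ib)], len(pairs)


def coloc_pair(
    a: SignalLBF,
    b: SignalLBF,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> ColocResult:
    """Posterior over H0-H4 for a pair of signals (log-space throughout)."""
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not (0 < p < 1):
            raise ColocError(f"prior {name}={p} outside (0, 1)")
    l1, l2, q = _align(a, b)
    if q < MIN_SHARED_WARN:
        logger.warning(
            "%s vs %s: only %d shared variants", a.signal_id, b.signal_id, q
        )
    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    s0 = 0.0
    s1 = lse1 + np.log(p1)
    s2 = lse2 + np.log(p2)
    s4 = lse12 + np.log(p12)
    # S3: log(exp(lse1 + lse2) - exp(lse12)), guarded
    tot = lse1 + lse2
    if lse12 >= tot - S3_GUARD_TOL:
        s3 = -np.inf
    else:
        s3 = tot + np.log1p(-np.exp(lse12 - tot)) + np.log(p1) + np.log(p2)

    pps = softmax(np.array([s0, s1, s2, s3, s4]))
    return ColocResult(
        signal_a=a.signal_id,
        signal_b=b.signal_id,
        pp0=float(pps[0]),
        pp1=float(pps[1]),
        pp2=float(pps[2]),
        pp3=float(pps[3]),
        pp4=float(pps[4]),
        n_shared_variants=q,
        p1=p1,
        p2=p2,
        p12=p12,
        low_overlap=q < MIN_SHARED_WARN,
    )


def coloc_all_pairs(
    gwas_signals: list[SignalLBF],
    qtl_signals: list[SignalLBF],
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    pp4_threshold: float = 0.9,
    max_signals_per_locus: int = 10,
) -> pd.DataFrame:
    """All-pairs colocalisation table with a strict PP4 pass flag.

    Each side is capped at ``max_signals_per_locus`` signals (extras are
    dropped with a notice). Pairs without shared variants are skipped and
    counted. ``pass`` is True only when pp4 strictly exceeds the threshold.
    """
    if not gwas_signals or not qtl_signals:
        raise ColocError("signal lists must be non-empty")

    def cap(signals: list[SignalLBF], label: str) -> list[SignalLBF]:
        if len(signals) > max_signals_per_locus:
            logger.warning(
                "%s: %d signals, using first %d",
                label, len(signals), max_signals_per_locus,
            )
            return signals[:max_signals_per_locus]
        return signals

    rows = []
    n_skipped = 0
    for g in cap(gwas_signals, "gwas"):
        for q in cap(qtl_signals, "qtl"):
            try:
                r = coloc_pair(g, q, p1=p1, p2=p2, p12=p12)
            except ColocError:
                n_skipped += 1
                continue
            rows.append(
                {
                    "gwas_signal": r.signal_a,
                    "qtl_signal": r.signal_b,
                    "nsnps": r.n_shared_variants,
                    "pp0": r.pp0,
                    "pp1": r.pp1,
                    "pp2": r.pp2,
                    "pp3": r.pp3,
                    "pp4": r.pp4,
                    "pass": r.pp4 > pp4_threshold,
                }
            )
    if n_skipped:
        logger.info("skipped %d pairs with no variant overlap", n_skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "gwas_signal", "qtl_signal", "nsnps",
            "pp0", "pp1", "pp2", "pp3", "pp4", "pass",
        ],
    )
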