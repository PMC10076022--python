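"""Independent brute-force oracles.

Every function here recomputes a statistic by direct enumeration of its
definition (explicit loops, no shared code with the package paths they
check). They are deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# DNB module indices
# ---------------------------------------------------------------------------


def module_indices_oracle(
    frame: pd.DataFrame,
    stage_samples: list[str],
    ref_samples: list[str],
    members: list[str],
    eps: float = 1e-8,
    sd_scale: str = "reference",
) -> tuple[float, float, float, float]:
    """(sd_avg, pcc_in, pcc_out, ci) by exhaustive pair enumeration."""

    def abs_r(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return abs(float(np.corrcoef(x, y)[0, 1]))

    X = frame[stage_samples]
    others = [g for g in frame.index if g not in members]
    sds = {}
    for g in frame.index:
        sd = float(np.std(X.loc[g].to_numpy(), ddof=1))
        if sd_scale == "reference":
            ref_sd = float(np.std(frame.loc[g, ref_samples].to_numpy(), ddof=1))
            sd = sd / ref_sd if ref_sd > 0 else sd
        sds[g] = sd
    sd_avg = float(np.mean([sds[g] for g in members]))
    in_pairs = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            in_pairs.append(abs_r(X.loc[a].to_numpy(), X.loc[b].to_numpy()))
    pcc_in = float(np.mean(in_pairs))
    out_pairs = []
    for a in members:
        for b in others:
            out_pairs.append(abs_r(X.loc[a].to_numpy(), X.loc[b].to_numpy()))
    pcc_out = float(np.mean(out_pairs))
    ci = sd_avg * pcc_in / max(pcc_out, eps)
    return sd_avg, pcc_in, pcc_out, ci


# ---------------------------------------------------------------------------
# DIRAC
# ---------------------------------------------------------------------------


def rank_template_oracle(
    frame: pd.DataFrame, samples: list[str]
) -> list[tuple[str, str]]:
    """Majority ordering by explicit counting; ties -> lexicographic first."""
    genes = sorted(frame.index)
    pairs = []
    n = len(samples)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            fwd = sum(frame.loc[a, s] > frame.loc[b, s] for s in samples)
            rev = sum(frame.loc[b, s] > frame.loc[a, s] for s in samples)
            if fwd * 2 > n:
                pairs.append((a, b))
            elif rev * 2 > n:
                pairs.append((b, a))
            else:
                pairs.append((a, b))
    return pairs


def matching_score_oracle(values: pd.Series, pairs: list[tuple[str, str]]) -> float:
    hits = sum(1 for a, b in pairs if values[a] > values[b])
    return hits / len(pairs)


def rci_oracle(frame: pd.DataFrame, samples: list[str]) -> float:
    pairs = rank_template_oracle(frame, samples)
    scores = [matching_score_oracle(frame[s], pairs) for s in samples]
    return float(np.mean(scores))


def rmsd_oracle(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    for xi, yi in zip(x, y):
        total += (np.log2(xi) - np.log2(yi)) ** 2
    return float(np.sqrt(total / len(x)))


# ---------------------------------------------------------------------------
# ssGSEA running sum
# ---------------------------------------------------------------------------


def ssgsea_sample_oracle(
    values: pd.Series, set_genes: set[str], alpha: float
) -> float:
    """One sample's raw running-sum score, step by step."""
    genes = list(values.index)
    n = len(genes)
    ranks = rankdata(-values.to_numpy(), method="average")
    stat = {g: n + 1.0 - r for g, r in zip(genes, ranks)}
    walk = list(genes)                   # ties keep original row order
    walk.sort(key=lambda g: -values[g])  # python sort is stable
    m = sum(1 for g in genes if g in set_genes)
    total_w = sum(stat[g] ** alpha for g in walk if g in set_genes)
    cum_in = 0.0
    cum_out = 0
    es = 0.0
    for g in walk:
        if g in set_genes:
            cum_in += stat[g] ** alpha
        else:
            cum_out += 1
        es += cum_in / total_w - cum_out / (n - m)
    return es


def preranked_es_oracle(
    stats_desc: np.ndarray, in_set: np.ndarray
) -> float:
    """Classic GSEA running sum on a pre-sorted ranking."""
    n = len(stats_desc)
    m = int(in_set.sum())
    total = float(np.sum(np.abs(stats_desc)[in_set]))
    running = 0.0
    best = 0.0
    for i in range(n):
        if in_set[i]:
            running += abs(stats_desc[i]) / total if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


# ---------------------------------------------------------------------------
# nearest shrunken centroids (literal equations)
# ---------------------------------------------------------------------------


class NSCOracle:
    """Direct transcription of the shrunken-centroid equations."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.classes = sorted(set(y))
        P, n = X.shape
        K = len(self.classes)
        self.overall = np.array([np.mean(X[i]) for i in range(P)])
        self.cent = {}
        self.n_k = {}
        for c in self.classes:
            cols = [j for j in range(n) if y[j] == c]
            self.n_k[c] = len(cols)
            self.cent[c] = np.array([np.mean(X[i, cols]) for i in range(P)])
        ss = np.zeros(P)
        for c in self.classes:
            cols = [j for j in range(n) if y[j] == c]
            for i in range(P):
                for j in cols:
                    ss[i] += (X[i, j] - self.cent[c][i]) ** 2
        self.s = np.sqrt(ss / (n - K))
        self.s0 = float(np.median(self.s))
        self.prior = {c: self.n_k[c] / n for c in self.classes}
        self.m = {c: np.sqrt(1.0 / self.n_k[c] - 1.0 / n) for c in self.classes}
        self.d = {
            c: (self.cent[c] - self.overall)
            / np.maximum(self.m[c] * (self.s + self.s0), 1e-12)
            for c in self.classes
        }

    def shrunken_centroid(self, c: str, delta: float) -> np.ndarray:
        d = self.d[c]
        d_sh = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        return self.overall + self.m[c] * (self.s + self.s0) * d_sh

    def discriminant(self, x: np.ndarray, c: str, delta: float) -> float:
        cent = self.shrunken_centroid(c, delta)
        total = 0.0
        for i in range(len(x)):
            total += (x[i] - cent[i]) ** 2 / max(self.s[i] + self.s0, 1e-12) ** 2
        return total - 2.0 * np.log(self.prior[c])

    def predict(self, X_new: np.ndarray, delta: float) -> list[str]:
        """Argmin of the discriminant; scores within 1e-9 of the minimum are
        ties resolved to the first class in sorted order."""
        out = []
        for j in range(X_new.shape[1]):
            scores = {c: self.discriminant(X_new[:, j], c, delta)
                      for c in self.classes}
            best = min(scores.values())
            out.append(next(c for c in self.classes
                            if scores[c] <= best + 1e-9))
        return out
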