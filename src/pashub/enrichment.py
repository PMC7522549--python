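"""Preranked gene-set enrichment on the mRNA-protein correlation ranking.

Genes are ordered by their cross-omics Pearson correlation and each gene set
is scored with the weighted Kolmogorov-Smirnov running sum: walking down the
ranking, set members add |score|^weight (normalised by the set's total) and
non-members subtract 1/(N - set size); the enrichment score (ES) is the
running-sum value of maximal absolute deviation. Significance comes from a
gene-label permutation null (set membership randomised over the list,
size-preserving), the standard convention for preranked analyses where no
phenotype remains to permute. NES and FDR q follow the sign-stratified
scheme: NES = ES / mean(|null ES| of matching sign), q compares the pooled
null NES distribution with the observed NES distribution within each sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending score; ties broken by gene id."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: pd.Series | dict) -> "RankedList":
        s = pd.Series(scores, dtype=float)
        if s.index.duplicated().any():
            raise ValueError("duplicate gene ids in ranking")
        if s.isna().any():
            raise ValueError("scores must be finite")
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        return cls(tuple(order), s.loc[order].to_numpy())

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentScore:
    es: float
    running: np.ndarray
    leading_edge: list[str]


def _positions(ranked: RankedList, members: set[str]) -> np.ndarray:
    idx = [i for i, g in enumerate(ranked.gene_ids) if g in members]
    return np.asarray(idx, dtype=np.int64)


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n: int
) -> tuple[float, int]:
    """ES and extremum position from sorted 0-based hit positions.

    The running sum's extrema occur immediately after a hit (maximum
    candidates) or immediately before one (minimum candidates), so only O(k)
    values need inspection. ``weights`` are |score|^weight at the hit
    positions. Ties between the positive and negative extreme break to the
    positive side for determinism.
    """
    k = len(pos)
    w = weights
    total = w.sum()
    if total <= 0:  # all-zero hit weights: fall back to unweighted steps
        w = np.ones(k)
        total = float(k)
    hits = np.cumsum(w) / total
    miss_step = 1.0 / (n - k)
    misses_before = pos - np.arange(k)  # number of misses preceding each hit
    after = hits - misses_before * miss_step
    before = np.concatenate(([0.0], hits[:-1])) - misses_before * miss_step
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = float(after[i_max])
    es_neg = float(before[i_min])
    # positive side wins exact ties; 1e-12 absorbs accumulation noise
    if max(es_pos, 0.0) + 1e-12 >= -min(es_neg, 0.0):
        return es_pos, i_max
    return es_neg, i_min


def enrichment_score(
    ranked: RankedList, gene_set: set[str] | list[str], weight: float = 1.0
) -> EnrichmentScore:
    """Weighted-KS enrichment score with full running profile and leading edge."""
    members = set(gene_set)
    n = len(ranked)
    pos = _positions(ranked, members)
    k = len(pos)
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if k == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.scores[pos]) ** weight
    es, i_ext = _es_from_positions(pos, w, n)
    # Full running profile (for inspection/plotting and the conservation check).
    steps = np.full(n, -1.0 / (n - k))
    wt = w if w.sum() > 0 else np.ones(k)
    steps[pos] = wt / wt.sum()
    running = np.cumsum(steps)
    if es >= 0:
        lead_pos = pos[: i_ext + 1]
    else:
        lead_pos = pos[i_ext:]
    leading = [ranked.gene_ids[i] for i in lead_pos]
    return EnrichmentScore(es=es, running=running, leading_edge=leading)


def _null_es(
    n: int, k: int, abs_weights_all: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for random size-k member sets over an N-long ranking."""
    out = np.empty(n_perm)
    for j in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        out[j], _ = _es_from_positions(pos, abs_weights_all[pos], n)
    return out


def gsea_preranked(
    ranked: RankedList,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every gene set against the ranking with a permutation null."""
    n = len(ranked)
    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** weight
    listed = set(ranked.gene_ids)

    kept: list[tuple[str, set[str]]] = []
    for set_id, members in sorted(gene_sets.items()):
        inter = set(members) & listed
        if min_size <= len(inter) < n:
            kept.append((set_id, inter))
    if not kept:
        raise ValueError(f"no gene set passes min_size={min_size} after intersection")

    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    all_null_nes: list[np.ndarray] = []
    for set_id, members in kept:
        k = len(members)
        if k not in null_by_size:
            null_by_size[k] = _null_es(n, k, abs_w, n_perm, rng)
        null = null_by_size[k]
        score = enrichment_score(ranked, members, weight=weight)
        es = score.es
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            nes = np.nan
            p = 1.0 / n_perm
        else:
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else np.nan
            if es >= 0:
                b = int((same_sign >= es).sum())
            else:
                b = int((same_sign <= es).sum())
            # no null as extreme: report the 1/n_perm resolution floor
            p = b / len(same_sign) if b > 0 else 1.0 / n_perm
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, -np.abs(null) / neg_mean)
        all_null_nes.append(null_nes[np.isfinite(null_nes)])
        rows.append(
            {
                "set_id": set_id,
                "size": k,
                "es": es,
                "nes": nes,
                "p_perm": float(p),
                "leading_edge": ",".join(score.leading_edge),
            }
        )
    res = pd.DataFrame(rows)
    pooled = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    obs = res["nes"].to_numpy()
    q = np.ones(len(res))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = float((pooled >= nes).mean()) if (pooled >= 0).any() else 1.0
            obs_frac = float((obs[np.isfinite(obs)] >= nes).mean())
        else:
            null_frac = float((pooled <= nes).mean()) if (pooled < 0).any() else 1.0
            obs_frac = float((obs[np.isfinite(obs)] <= nes).mean())
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    res["fdr_q"] = q
    return res


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: set_id <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            set_id, members = parts[0], {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"empty gene set {set_id!r}")
            sets[set_id] = members
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            fh.write("\t".join([set_id, description, *sorted(sets[set_id])]) + "\n")
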