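"""Burden-preserving permutation tests for acquired-mutation recurrence.

Recurrence of a gene is the number of replicate tumors in which it is
mutated; pathway recurrence counts tumors with at least one mutated member
gene.  The null preserves each tumor's mutation burden: every permutation
redraws each tumor's mutated gene set uniformly without replacement from a
shared background universe of expressed genes, at the observed set size.
Empirical p-values are the fraction of permutations with recurrence at least
as high as observed (per item, or of the genome-wide maximum for a global
test), with Benjamini–Hochberg FDR across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class MutationProfiles:
    """Per-tumor mutated gene sets over a background universe."""

    tumors: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.tumors = {t: frozenset(g) for t, g in self.tumors.items()}
        self.universe = frozenset(self.universe)
        for t, genes in self.tumors.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"tumor {t}: genes outside universe: {sorted(extra)[:3]}")

    @property
    def burdens(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.tumors.items()}


def read_profiles_tsv(path: str, universe: Sequence[str]) -> MutationProfiles:
    """Two-column TSV (tumor_id, gene); one row per mutated gene occurrence."""
    df = pd.read_csv(path, sep="\t", header=0)
    tumors: dict[str, set[str]] = {}
    for tumor, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        tumors.setdefault(str(tumor), set()).add(str(gene))
    return MutationProfiles({t: frozenset(g) for t, g in tumors.items()}, frozenset(universe))


def read_gmt(path: str) -> dict[str, frozenset[str]]:
    """GMT pathway file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = frozenset(g for g in parts[2:] if g)
    return out


def observed_recurrence(
    profiles: MutationProfiles,
    pathways: Mapping[str, frozenset[str]] | None = None,
) -> pd.Series:
    """Recurrence counts: per gene, or per pathway when a map is given.

    Pathway genes outside the universe are dropped before counting.
    """
    if not profiles.tumors:
        raise ValueError("at least one tumor required")
    if pathways is None:
        counts: dict[str, int] = {}
        for genes in profiles.tumors.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        full = {g: counts.get(g, 0) for g in sorted(profiles.universe)}
        return pd.Series(full, name="recurrence")
    out = {}
    for name, members in pathways.items():
        members = members & profiles.universe
        out[name] = sum(1 for genes in profiles.tumors.values() if genes & members)
    return pd.Series(out, name="recurrence")


def permute_once(
    universe: Sequence[str], burdens: Mapping[str, int], rng: np.random.Generator
) -> MutationProfiles:
    """One burden-preserving randomization of all tumors' gene sets."""
    uni = sorted(set(universe))
    for t, b in burdens.items():
        if b > len(uni):
            raise ValueError(f"tumor {t}: burden {b} exceeds universe size {len(uni)}")
    tumors = {
        t: frozenset(uni[i] for i in rng.choice(len(uni), size=b, replace=False))
        for t, b in burdens.items()
    }
    return MutationProfiles(tumors, frozenset(uni))


@dataclass
class RecurrenceResult:
    table: pd.DataFrame  # index item; columns recurrence, p, (q for pathways)
    mode: str
    n_perm: int
    max_statistic_p: float | None = None


def empirical_p(
    profiles: MutationProfiles,
    pathways: Mapping[str, frozenset[str]] | None = None,
    n_perm: int = 10_000,
    mode: str = "per_item",
    seed: int = 0,
    add_one: bool = False,
) -> RecurrenceResult:
    """Permutation p-values for gene- or pathway-level recurrence.

    ``per_item``: p_x = #{b : R_x^(b) ≥ R_x^obs} / B for every item.
    ``max_statistic``: a single global p for the maximum recurrence across
    items (family-wide test of any convergence at all).
    ``add_one`` applies (r+1)/(B+1) smoothing to avoid exact zeros.
    Burden preservation is asserted on every draw.  BH q-values are attached
    for pathway tables (per-item mode).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("per_item", "max_statistic"):
        raise ValueError("mode must be 'per_item' or 'max_statistic'")
    rng = np.random.default_rng(seed)
    obs = observed_recurrence(profiles, pathways)
    burdens = profiles.burdens
    universe = sorted(profiles.universe)
    uni_index = {g: i for i, g in enumerate(universe)}

    if pathways is not None:
        member_idx = [
            np.fromiter(
                (uni_index[g] for g in (genes & profiles.universe)), dtype=np.int64
            )
            for genes in pathways.values()
        ]
    obs_vec = obs.to_numpy()
    ge_counts = np.zeros(obs_vec.size, dtype=np.int64)
    max_obs = int(obs_vec.max()) if obs_vec.size else 0
    max_ge = 0
    n_uni = len(universe)
    burden_sizes = list(burdens.values())

    for _ in range(n_perm):
        # membership counts per gene for this permutation
        rec = np.zeros(n_uni, dtype=np.int64)
        draws = []
        for b in burden_sizes:
            idx = rng.choice(n_uni, size=b, replace=False)
            assert idx.size == b  # burden preserved by construction
            rec[idx] += 1
            draws.append(idx)
        if pathways is None:
            perm_vec = rec
        else:
            perm_vec = np.array(
                [
                    sum(1 for idx in draws if np.any(np.isin(idx, m, assume_unique=True)))
                    if m.size
                    else 0
                    for m in member_idx
                ],
                dtype=np.int64,
            )
        ge_counts += perm_vec >= obs_vec
        if perm_vec.size and perm_vec.max() >= max_obs:
            max_ge += 1

    if add_one:
        p_item = (ge_counts + 1) / (n_perm + 1)
        p_max = (max_ge + 1) / (n_perm + 1)
    else:
        p_item = ge_counts / n_perm
        p_max = max_ge / n_perm

    table = pd.DataFrame({"recurrence": obs_vec, "p": p_item}, index=obs.index)
    if mode == "per_item" and pathways is not None:
        table["q"] = bh_fdr(table["p"].to_numpy())
    return RecurrenceResult(
        table=table,
        mode=mode,
        n_perm=n_perm,
        max_statistic_p=float(p_max),
    )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone-corrected)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
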