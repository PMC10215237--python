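"""Overlap and over-representation statistics for target/disease gene sets.

Two related questions are answered here.  First, do a compound's (or an
herb's key-) targets overlap a disease protein set more than chance?  That
is tested exactly with the upper-tail hypergeometric distribution and,
following common practice in network pharmacology, also against an explicit
randomization null: size-matched target sets are drawn repeatedly from the
background and the observed overlap is expressed as a fold change over the
mean random overlap.  Second, which pathways from a gene-set library are
over-represented among the key targets?  That is one hypergeometric test
per set with Benjamini-Hochberg (default) or Bonferroni correction, plus an
Enrichr-style combined score -ln(p) * z where z is the standardized overlap
under the hypergeometric null (k - nK/N) / sigma.

All computation is local and exact; no web enrichment service is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    """Named gene sets (e.g. pathways) over protein identifiers."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")


def read_gmt(path, source: str | None = None) -> GeneSetLibrary:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = {m for m in parts[2:] if m}
    if not sets:
        raise ValidationError(f"GMT file {path} contains no gene sets")
    return GeneSetLibrary(sets=sets, source=source or str(path))


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(library.sets):
            members = "\t".join(sorted(library.sets[name]))
            fh.write(f"{name}\t{library.source or 'na'}\t{members}\n")


@dataclass
class EnrichmentResult:
    """One overlap test: counts, exact p, and derived scores."""

    name: str
    overlap_k: int
    query_n: int
    set_K: int
    background_N: int
    p_value: float
    adjusted_p: float = math.nan
    z_score: float = math.nan
    combined_score: float = math.nan
    fold_enrichment: float = math.nan
    empirical_p: float = math.nan
    overlap_members: set[str] = field(default_factory=set)
    notes: list[str] = field(default_factory=list)


def _resolve_query(query, background, *, strict: bool, label: str):
    query, background = set(query), set(background)
    if not background:
        raise ValidationError("background set is empty")
    outside = query - background
    if outside:
        msg = (
            f"{label}: {len(outside)} query id(s) outside background: "
            f"{', '.join(sorted(outside)[:8])}"
        )
        if strict:
            raise ValidationError(msg)
        logger.warning("%s (dropped)", msg)
    return query & background, background


def hypergeom_overlap_test(
    query,
    reference,
    background,
    name: str = "overlap",
    strict: bool = False,
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test P(X >= k).

    With N = |background|, K = |reference ∩ background|, n = |query| and
    k = |query ∩ reference|, the p-value is the exact tail sum of the
    hypergeometric pmf (no normal approximation).  Also fills the
    hypergeometric z-score, the Enrichr-style combined score -ln(p) * z,
    and the expectation-based fold enrichment k / (nK/N).
    """
    query, background = _resolve_query(query, background, strict=strict, label=name)
    reference = set(reference) & background
    n_q, big_k, big_n = len(query), len(reference), len(background)
    overlap = query & reference
    k = len(overlap)
    # P(X >= k); sf(k-1) is an exact tail sum in scipy
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_q))
    p = min(max(p, 0.0), 1.0) or 1e-320  # guard exact-zero underflow
    mu = n_q * big_k / big_n
    var = (
        n_q * (big_k / big_n) * (1 - big_k / big_n) * (big_n - n_q) / max(big_n - 1, 1)
    )
    notes: list[str] = []
    if var > 0:
        z = (k - mu) / math.sqrt(var)
        combined = -math.log(p) * z
    else:
        z = math.nan
        combined = 0.0
        notes.append("sigma=0: z undefined, combined_score set to 0")
    fold = k / mu if mu > 0 else math.inf if k > 0 else math.nan
    return EnrichmentResult(
        name=name,
        overlap_k=k,
        query_n=n_q,
        set_K=big_k,
        background_N=big_n,
        p_value=p,
        z_score=z,
        combined_score=combined,
        fold_enrichment=fold,
        overlap_members=overlap,
        notes=notes,
    )


@dataclass
class MonteCarloFold:
    """Randomization-null fold enrichment of an observed overlap."""

    fold: float
    empirical_p: float
    observed: int
    mean_random_overlap: float
    n_iter: int
    infinite: bool = False


def monte_carlo_fold_enrichment(
    query,
    reference,
    background,
    n_iter: int = 10_000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> MonteCarloFold:
    """Fold enrichment against size-matched random target draws.

    Repeatedly draws |query| ids uniformly without replacement from the
    background and counts the overlap with ``reference``; the observed
    overlap divided by the mean random overlap is the fold, and
    empirical_p = (1 + #{random >= observed}) / (n_iter + 1).
    """
    if n_iter < 100:
        raise ValidationError("n_iter must be >= 100")
    query, background_set = _resolve_query(query, background, strict=False, label="mc-fold")
    reference = set(reference) & background_set
    bg = sorted(background_set)
    ref_mask = np.fromiter((b in reference for b in bg), dtype=bool, count=len(bg))
    n = len(query)
    observed = len(query & reference)
    rng = rng if rng is not None else np.random.default_rng(seed)
    draws = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        pick = rng.choice(len(bg), size=n, replace=False)
        draws[i] = int(ref_mask[pick].sum())
    mean_random = float(draws.mean())
    empirical_p = float((1 + int((draws >= observed).sum())) / (n_iter + 1))
    if mean_random == 0:
        logger.warning("mean random overlap is 0; fold reported as infinite")
        return MonteCarloFold(
            fold=math.inf,
            empirical_p=empirical_p,
            observed=observed,
            mean_random_overlap=0.0,
            n_iter=n_iter,
            infinite=True,
        )
    return MonteCarloFold(
        fold=observed / mean_random,
        empirical_p=empirical_p,
        observed=observed,
        mean_random_overlap=mean_random,
        n_iter=n_iter,
    )


def _validate_p(p_values) -> np.ndarray:
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = _validate_p(p_values)
    if p.size == 0:
        return []
    return multipletests(p, method="fdr_bh")[1].tolist()


def bonferroni_adjust(p_values) -> list[float]:
    """Bonferroni adjustment min(1, m * p)."""
    p = _validate_p(p_values)
    if p.size == 0:
        return []
    return np.minimum(1.0, p * p.size).tolist()


_CORRECTIONS = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}


def pathway_ora(
    query,
    library: GeneSetLibrary,
    background,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Over-representation analysis: one hypergeometric test per gene set.

    Results are sorted by adjusted p-value, ties broken by set name.
    """
    if not library.sets:
        raise ValidationError("gene set library is empty")
    if correction not in _CORRECTIONS:
        raise ValidationError(f"unknown correction {correction!r}; use bh or bonferroni")
    results = [
        hypergeom_overlap_test(query, members, background, name=name)
        for name, members in sorted(library.sets.items())
    ]
    adjusted = _CORRECTIONS[correction]([r.p_value for r in results])
    for res, adj in zip(results, adjusted):
        res.adjusted_p = float(adj)
    return sorted(results, key=lambda r: (r.adjusted_p, r.name))


def write_ora_tsv(results: list[EnrichmentResult], path, correction: str = "bh") -> None:
    """Pathway-table export: term, overlap k/K, adjusted p, combined score, genes."""
    with open(path, "w") as fh:
        fh.write(
            "term\toverlap\tp_value\t"
            f"adjusted_p_{correction}\tcombined_score\tgenes\n"
        )
        for r in results:
            genes = ";".join(sorted(r.overlap_members))
            fh.write(
                f"{r.name}\t{r.overlap_k}/{r.set_K}\t{r.p_value:.6g}\t"
                f"{r.adjusted_p:.6g}\t{r.combined_score:.4f}\t{genes}\n"
            )
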