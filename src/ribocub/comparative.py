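"""Cross-species layer: tRNA pools, concordance, regressions, clustering, GC.

The size of a species' tRNA pool is approximated by its tRNA gene copy
number.  A codon's cognate tRNA is the one whose anticodon is the exact
reverse complement of the codon (strict Watson–Crick pairing; wobble decoding
is deliberately not modelled).  Codons with zero cognate gene copies
("codons lacking tRNA") must be wobble-decoded.

Species are compared by (i) concordance between each amino acid's preferred
codon and the codon with the most cognate tRNA gene copies, (ii) OLS
regressions of codon-lacking counts on pool size, (iii) UPGMA trees built on
Canberra distances between per-species vectors (anticodon copy numbers or
59-codon RSCU), and (iv) genome GC content versus the GC share of preferred
codons' third position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import canberra as _scipy_canberra

from .genetic_code import BASES, STANDARD_CODE, GeneticCode
from .rscu import RSCUVector

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# tRNA pools


@dataclass
class TRNAPool:
    """tRNA gene copy counts per anticodon (DNA alphabet)."""

    copies: dict[str, int]

    def __post_init__(self) -> None:
        for anticodon, n in self.copies.items():
            if len(anticodon) != 3 or any(b not in BASES for b in anticodon):
                raise ValueError(f"invalid anticodon {anticodon!r}")
            if n < 0:
                raise ValueError(f"negative copy count for {anticodon}")

    @property
    def total(self) -> int:
        return sum(self.copies.values())

    def cognate_copies(self, codon: str) -> int:
        """Gene copies of the strict Watson–Crick cognate tRNA of `codon`."""
        return self.copies.get(cognate_codon(codon), 0)


def cognate_codon(anticodon: str) -> str:
    """The codon read by an anticodon: its reverse complement (and vice versa)."""
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or any(b not in BASES for b in anticodon):
        raise ValueError(f"not a DNA triplet: {anticodon!r}")
    return anticodon.translate(_COMPLEMENT)[::-1]


def read_trna_tsv(path) -> TRNAPool:
    """Read a TSV with columns (anticodon, copy_count); isodecoder rows with
    the same anticodon are summed."""
    df = pd.read_csv(path, sep="\t")
    if not {"anticodon", "copy_count"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["anticodon", "copy_count"])
    grouped = df.groupby("anticodon")["copy_count"].sum()
    return TRNAPool({str(a).upper(): int(n) for a, n in grouped.items()})


def write_trna_tsv(pool: TRNAPool, path) -> None:
    pd.DataFrame(
        sorted(pool.copies.items()), columns=["anticodon", "copy_count"]
    ).to_csv(path, sep="\t", index=False)


def codons_lacking_trna(pool: TRNAPool, code: GeneticCode = STANDARD_CODE) -> set[str]:
    """Analysis codons whose strict cognate anticodon has zero gene copies."""
    return {c for c in code.analysis_codons if pool.cognate_copies(c) == 0}


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_fav_lacking: int
    missing_aas: tuple[str, ...] = ()


def favourite_concordance(
    preferred: Mapping[str, str],
    pool: TRNAPool,
    code: GeneticCode = STANDARD_CODE,
) -> ConcordanceResult:
    """How many preferred codons carry the highest cognate tRNA copy number.

    Per degenerate amino acid the preferred codon is concordant iff its
    cognate copy count equals the maximum cognate count among the amino
    acid's synonyms (ties at the maximum count as concordant).  Amino acids
    missing from `preferred` count as non-concordant and are reported.
    `n_fav_lacking` counts preferred codons with zero cognate copies.
    """
    n_concordant = 0
    n_fav_lacking = 0
    missing = []
    for aa in code.degenerate_aas:
        pref = preferred.get(aa)
        pref = getattr(pref, "codon", pref)
        if pref is None:
            missing.append(aa)
            continue
        cognates = {c: pool.cognate_copies(c) for c in code.synonyms(aa)}
        if cognates[pref] == max(cognates.values()):
            n_concordant += 1
        if cognates[pref] == 0:
            n_fav_lacking += 1
    if missing:
        logger.warning("no preferred codon for %s; counted non-concordant", missing)
    return ConcordanceResult(n_concordant, n_fav_lacking, tuple(missing))


# ---------------------------------------------------------------------------
# regression


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def ols_regression(
    points: Mapping[str, tuple[float, float]],
    exclude: Iterable[str] = (),
) -> RegressionResult:
    """Ordinary least squares y ~ x over species points, minus exclusions."""
    exclude = set(exclude)
    kept = [(x, y) for s, (x, y) in points.items() if s not in exclude]
    if len(kept) < 3:
        raise ValueError("need at least 3 points after exclusion")
    x, y = np.array(kept, dtype=float).T
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


# ---------------------------------------------------------------------------
# clustering


def canberra_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Canberra distance Σ |x−y| / (|x|+|y|); 0/0 terms contribute 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    return float(_scipy_canberra(x, y))


@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Rooted ultrametric tree; node height = merge distance / 2."""

    root: TreeNode
    labels: tuple[str, ...]

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{length:.12g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.12g}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def leaf_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                out[node.name] = depth
            for c in node.children:
                walk(c, depth + node.height - c.height)

        walk(self.root, 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def upgma(d: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """UPGMA (average-linkage) clustering of a symmetric distance matrix.

    The closest pair of clusters is merged at node height d/2; distances to
    the merged cluster are size-weighted arithmetic means.  Ties on distance
    are broken by the smallest (lexicographic) pair of cluster labels, where
    a cluster is labelled by its smallest leaf, so the tree is deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = {i: TreeNode(0.0, name=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (i, j) = min(
            dist,
            key=lambda p: (dist[p], *sorted((minlab[p[0]], minlab[p[1]]))),
        )
        h = dist[(i, j)] / 2
        merged = TreeNode(h, children=(nodes[i], nodes[j]))
        others = [k for k in nodes if k not in (i, j)]
        for k in others:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        minlab[next_id] = min(minlab.pop(i), minlab.pop(j))
        del nodes[i], nodes[j]
        nodes[next_id] = merged
        next_id += 1
    return Dendrogram(nodes.popitem()[1], tuple(labels))


def distance_matrix(
    vectors: Mapping[str, Sequence[float]],
    metric=canberra_distance,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pairwise distance matrix over labelled vectors (label-sorted)."""
    labels = tuple(sorted(vectors))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = metric(vectors[labels[i]], vectors[labels[j]])
    return d, labels


# ---------------------------------------------------------------------------
# GC statistics and per-species summary


def gc_stats(
    sequences: Mapping[str, str] | Iterable[str] | str,
    preferred: Mapping[str, str],
    code: GeneticCode = STANDARD_CODE,
) -> tuple[float, float]:
    """(genome GC%, GC% of the last base of preferred codons).

    Genome GC% counts G+C over A/C/G/T of the provided sequences; the
    last-base statistic is the percentage of the 18 preferred codons ending
    in G or C.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    elif isinstance(sequences, Mapping):
        sequences = sequences.values()
    counts = {b: 0 for b in BASES}
    for seq in sequences:
        up = seq.upper()
        for b in BASES:
            counts[b] += up.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no A/C/G/T bases in the provided sequences")
    genome_gc = 100.0 * (counts["G"] + counts["C"]) / total

    n_aas = len(code.degenerate_aas)
    missing = [aa for aa in code.degenerate_aas if aa not in preferred]
    if missing:
        logger.warning("preferred codon missing for %s; counted as not G/C-ending", missing)
    ends_gc = sum(
        1
        for aa in code.degenerate_aas
        if aa in preferred and getattr(preferred[aa], "codon", preferred[aa])[-1] in "GC"
    )
    return genome_gc, 100.0 * ends_gc / n_aas


@dataclass
class SpeciesSummary:
    """Per-species comparison of preferred codons against the tRNA pool."""

    species: str
    total_trnas: int
    n_concordant: int
    concordance_percent: float
    n_fav_lacking: int
    n_lacking: int
    preferred: dict[str, str] = field(default_factory=dict)
    genome_gc_percent: float | None = None
    preferred_lastbase_gc_percent: float | None = None

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "total_trnas": self.total_trnas,
            "n_concordant": self.n_concordant,
            "concordance_percent": self.concordance_percent,
            "n_fav_lacking": self.n_fav_lacking,
            "n_lacking": self.n_lacking,
            "genome_gc_percent": self.genome_gc_percent,
            "preferred_lastbase_gc_percent": self.preferred_lastbase_gc_percent,
        }


def concordance_percent(n_concordant: int, n_aas: int = 18) -> float:
    """Concordant share as a percentage with one decimal (e.g. 15/18 → 83.3)."""
    return float(f"{100.0 * n_concordant / n_aas:.1f}")


def species_summary(
    species: str,
    preferred: Mapping[str, str],
    pool: TRNAPool,
    gc_sequences: Mapping[str, str] | Iterable[str] | str | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> SpeciesSummary:
    """Assemble the per-species summary row."""
    conc = favourite_concordance(preferred, pool, code)
    genome_gc = lastbase_gc = None
    if gc_sequences is not None:
        genome_gc, lastbase_gc = gc_stats(gc_sequences, preferred, code)
    return SpeciesSummary(
        species=species,
        total_trnas=pool.total,
        n_concordant=conc.n_concordant,
        concordance_percent=concordance_percent(conc.n_concordant, len(code.degenerate_aas)),
        n_fav_lacking=conc.n_fav_lacking,
        n_lacking=len(codons_lacking_trna(pool, code)),
        preferred={aa: getattr(c, "codon", c) for aa, c in preferred.items()},
        genome_gc_percent=genome_gc,
        preferred_lastbase_gc_percent=lastbase_gc,
    )


def mean_rscu(vectors: Sequence[RSCUVector]) -> RSCUVector:
    """Average RSCU over replicates, per codon over replicates defining it."""
    if not vectors:
        raise ValueError("no vectors to average")
    code = vectors[0].code
    values: dict[str, float] = {}
    for c in code.analysis_codons:
        defined = [v.values[c] for v in vectors if c in v.values]
        if defined:
            values[c] = float(np.mean(defined))
    undefined = frozenset(
        aa for aa in code.degenerate_aas
        if all(c not in values for c in code.synonyms(aa))
    )
    return RSCUVector(values, undefined, code)


# ---------------------------------------------------------------------------
# published per-species tRNA summary (bundled reference table)


def load_species_trna_summary() -> pd.DataFrame:
    """Published per-species tRNA-pool summary bundled with the package.

    Columns: species, total_trnas, n_concordant, concordance_percent,
    n_fav_lacking, n_lacking — one row per species, including the
    H. capsulatum outlier conventionally excluded from the regressions.
    """
    with resources.files("ribocub.data").joinpath("species_trna_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
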