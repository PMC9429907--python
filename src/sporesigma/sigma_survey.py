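"""Homology-based classification of sigma-factor proteins.

Phage proteins are matched against bacterial sigma-factor family profiles
(TIGRFAM-style HMMs) upstream; this module consumes the tabular hit files,
applies the best-hit classification rule with its umbrella-family fallback,
flags sporulation-like proteins and genomes, summarizes the per-genome and
per-host-phylum distribution, and computes profile-alignment percent
identity in the esl-alipid convention.

The classification rule: a protein is assigned the family of its smallest
sequence E-value hit, *unless* that family is one of the two general
umbrella families (sigma70-ECF, SigBFG), in which case the next-best
non-general hit is taken if one exists.  A protein is sporulation-like if
its assigned family is in the catalog's spore-like set, and a genome is
flagged spore-like if any of its proteins is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FamilyCatalog",
    "DEFAULT_CATALOG",
    "HmmHit",
    "SigmaAssignment",
    "GenomeSummary",
    "ProfileAlignment",
    "parse_hmm_tblout",
    "classify_protein",
    "classify_table",
    "summarize_genomes",
    "percent_identity",
    "identity_phenotype_correlation",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class FamilyCatalog:
    """Sigma-factor family catalog with umbrella and sporulation flags.

    ``general`` families are broad profiles matched by nearly any sigma
    factor; they are never themselves informative about sporulation and by
    default are never spore-like.
    """

    families: tuple[str, ...]
    general: frozenset[str]
    spore_like: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.families)) != len(self.families):
            raise ValueError("family ids must be unique")
        fams = set(self.families)
        if not self.general <= fams or not self.spore_like <= fams:
            raise ValueError("general/spore-like sets must be subsets of the family list")

    def __contains__(self, family_id: str) -> bool:
        return family_id in set(self.families)

    def is_general(self, family_id: str) -> bool:
        return family_id in self.general

    def is_spore_like(self, family_id: str) -> bool:
        return family_id in self.spore_like

    @classmethod
    def from_csv(cls, path) -> "FamilyCatalog":
        """Load a catalog CSV with columns family_id, is_general, is_spore_like."""
        df = pd.read_csv(path)
        required = {"family_id", "is_general", "is_spore_like"}
        if not required <= set(df.columns):
            raise ValueError(f"catalog CSV must contain columns {sorted(required)}")
        return cls(
            families=tuple(df["family_id"].astype(str)),
            general=frozenset(df.loc[df["is_general"].astype(bool), "family_id"].astype(str)),
            spore_like=frozenset(df.loc[df["is_spore_like"].astype(bool), "family_id"].astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": self.families,
                "is_general": [f in self.general for f in self.families],
                "is_spore_like": [f in self.spore_like for f in self.families],
            }
        )


#: Default catalog: the sporulation cascade families (forespore sigF/sigG,
#: mother-cell sigE/sigK), a primary-sigma family, and the two umbrella
#: families.  Spore-like ids are configuration; real surveys supply their own
#: catalog CSV with the accessions they searched.
DEFAULT_CATALOG = FamilyCatalog(
    families=(
        "spore_sigF",
        "spore_sigE",
        "spore_sigG",
        "spore_sigK",
        "sigA_primary",
        "sigma70-ECF",
        "SigBFG",
    ),
    general=frozenset({"sigma70-ECF", "SigBFG"}),
    spore_like=frozenset({"spore_sigF", "spore_sigE", "spore_sigG", "spore_sigK"}),
)


@dataclass(frozen=True)
class HmmHit:
    protein_id: str
    family_id: str
    evalue: float
    score: float = math.nan

    def __post_init__(self) -> None:
        if not (self.evalue > 0):
            raise ValueError("sequence E-value must be positive")


@dataclass(frozen=True)
class SigmaAssignment:
    protein_id: str
    assigned_family: str | None
    spore_like: bool
    fallback_used: bool


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    host_phylum: str
    n_sigma: int
    spore_like_flag: bool


HIT_COLUMNS = ["protein_id", "family_id", "evalue", "score"]


def parse_hmm_tblout(stream: IO[str] | str | Iterable[str]) -> pd.DataFrame:
    """Parse an hmmscan ``--tblout``-style whitespace table into a hit table.

    Column convention (HMMER 3 target table): target/family name in column 1,
    query/protein name in column 3, full-sequence E-value in column 5, bit
    score in column 6; '#' lines are comments.  Per-domain repeats of the
    same (protein, family) pair are collapsed to the smallest sequence
    E-value at load time.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"line {lineno}: expected >= 6 whitespace-separated fields")
        family, protein = parts[0], parts[2]
        try:
            evalue = float(parts[4])
            score = float(parts[5])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
        if evalue <= 0:
            raise ValueError(f"line {lineno}: sequence E-value must be positive")
        rows.append((protein, family, evalue, score))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if df.empty:
        return df
    # keep best (smallest) sequence E-value per (protein, family); stable
    # w.r.t. original row order among the survivors
    best = df.sort_values("evalue", kind="stable").drop_duplicates(
        ["protein_id", "family_id"], keep="first"
    )
    return best.sort_index().reset_index(drop=True)


def _ordered_hits(hits: pd.DataFrame) -> pd.DataFrame:
    # smallest E-value first; ties broken by higher bit score, then family id
    h = hits.copy()
    h["_score"] = h["score"].fillna(-np.inf)
    h = h.sort_values(
        by=["evalue", "_score", "family_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    return h.drop(columns="_score")


def classify_protein(
    hits_for_one_protein: pd.DataFrame | Sequence[HmmHit],
    catalog: FamilyCatalog = DEFAULT_CATALOG,
) -> SigmaAssignment:
    """Assign a family to one protein by the best-hit rule with fallback.

    The best (smallest sequence E-value) hit wins; if it is a general
    umbrella family and a non-general hit exists, the best non-general hit
    is taken instead (``fallback_used``).  Proteins with only general hits
    keep the general assignment and are not spore-like.
    """
    if not isinstance(hits_for_one_protein, pd.DataFrame):
        hits_for_one_protein = pd.DataFrame(
            [(h.protein_id, h.family_id, h.evalue, h.score) for h in hits_for_one_protein],
            columns=HIT_COLUMNS,
        )
    hits = hits_for_one_protein
    if hits.empty:
        return SigmaAssignment("", None, False, False)
    proteins = hits["protein_id"].unique()
    if len(proteins) != 1:
        raise ValueError("classify_protein expects hits for exactly one protein")
    protein_id = str(proteins[0])
    unknown = set(hits["family_id"]) - set(catalog.families)
    if unknown:
        raise KeyError(f"unknown family ids: {sorted(unknown)}")
    ordered = _ordered_hits(hits)
    best_family = str(ordered.iloc[0]["family_id"])
    fallback = False
    if catalog.is_general(best_family):
        non_general = ordered[~ordered["family_id"].map(catalog.is_general)]
        if len(non_general):
            best_family = str(non_general.iloc[0]["family_id"])
            fallback = True
    return SigmaAssignment(protein_id, best_family, catalog.is_spore_like(best_family), fallback)


def classify_table(
    hit_table: pd.DataFrame, catalog: FamilyCatalog = DEFAULT_CATALOG
) -> pd.DataFrame:
    """Classify every protein in a hit table; one assignment row per protein."""
    records = []
    for protein_id, group in hit_table.groupby("protein_id", sort=False):
        a = classify_protein(group, catalog)
        records.append((a.protein_id, a.assigned_family, a.spore_like, a.fallback_used))
    return pd.DataFrame(
        records, columns=["protein_id", "assigned_family", "spore_like", "fallback_used"]
    )


def summarize_genomes(
    assignments: pd.DataFrame,
    genome_catalog: pd.DataFrame,
    min_phylum_genomes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-genome summaries plus sigma-count and per-phylum distributions.

    ``assignments`` needs columns genome_id, protein_id, spore_like (one row
    per classified protein); ``genome_catalog`` needs genome_id and
    host_phylum and must cover every genome referenced (genomes with no
    sigma factors appear only in the catalog and count as 0).

    Returns (genome_summaries, count_distribution, phylum_table).  The count
    distribution bins genomes by 0/1/2/3+ sigma factors, fractions summing
    to 1.  Phyla with fewer genomes than ``min_phylum_genomes`` are flagged
    (``low_count``) but retained.
    """
    cat = genome_catalog.copy()
    if not {"genome_id", "host_phylum"} <= set(cat.columns):
        raise ValueError("genome catalog needs genome_id and host_phylum columns")
    cat["genome_id"] = cat["genome_id"].astype(str)
    if cat["genome_id"].duplicated().any():
        raise ValueError("duplicate genome ids in catalog")
    asn = assignments.copy()
    if len(asn):
        asn["genome_id"] = asn["genome_id"].astype(str)
        missing = set(asn["genome_id"]) - set(cat["genome_id"])
        if missing:
            raise KeyError(f"genomes absent from catalog: {sorted(missing)}")
        per_genome = asn.groupby("genome_id").agg(
            n_sigma=("protein_id", "size"), spore_like_flag=("spore_like", "any")
        )
    else:
        per_genome = pd.DataFrame(columns=["n_sigma", "spore_like_flag"])
    summaries = cat.set_index("genome_id").join(per_genome)
    n_sigma = summaries["n_sigma"].to_numpy(dtype=float)
    summaries["n_sigma"] = np.nan_to_num(n_sigma, nan=0.0).astype(int)
    flag = summaries["spore_like_flag"].to_numpy(dtype=object)
    summaries["spore_like_flag"] = np.array([bool(v) if v == v else False for v in flag])
    summaries = summaries.reset_index()

    bins = summaries["n_sigma"].clip(upper=3)
    counts = bins.value_counts().reindex([0, 1, 2, 3], fill_value=0)
    dist = pd.DataFrame(
        {
            "n_sigma_bin": ["0", "1", "2", "3+"],
            "n_genomes": counts.to_numpy(),
            "fraction": counts.to_numpy() / max(len(summaries), 1),
        }
    )

    phylum = (
        summaries.groupby("host_phylum")
        .agg(
            n_genomes=("genome_id", "size"),
            n_spore_like=("spore_like_flag", "sum"),
            n_with_sigma=("n_sigma", lambda s: int((s > 0).sum())),
        )
        .reset_index()
    )
    phylum["low_count"] = phylum["n_genomes"] < min_phylum_genomes
    return summaries, dist, phylum


# ---------------------------------------------------------------------------
# profile-alignment percent identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileAlignment:
    """Aligned sequences with a per-column profile reference mask.

    The mask marks the profile's match (reference) columns; trimming removes
    alignment columns before the first and after the last reference column,
    emulating termini trimming against the profile.
    """

    sequences: Mapping[str, str]
    reference_mask: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have equal length")
        length = lengths.pop() if lengths else 0
        if not self.reference_mask:
            object.__setattr__(self, "reference_mask", tuple([True] * length))
        if len(self.reference_mask) != length:
            raise ValueError("reference mask length must equal alignment length")

    @classmethod
    def from_fasta(cls, path, mask_id: str = "RF", case_mask: bool = False) -> "ProfileAlignment":
        """Read an aligned FASTA.

        If a record named ``mask_id`` is present its 'x' characters define
        the reference columns.  With ``case_mask`` (A2M convention), a
        column is a reference column when any sequence shows an uppercase
        residue or '-' in it.
        """
        seqs: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        seqs[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks)
        mask: tuple[bool, ...] = ()
        if mask_id in seqs:
            mask = tuple(c == "x" for c in seqs.pop(mask_id))
        elif case_mask and seqs:
            length = len(next(iter(seqs.values())))
            mask = tuple(
                any(s[i] == "-" or s[i].isupper() for s in seqs.values()) for i in range(length)
            )
        return cls(sequences=seqs, reference_mask=mask)


def percent_identity(
    aln: ProfileAlignment, name_a: str, name_b: str, trim_to_reference: bool = True
) -> float:
    """Pairwise percent identity over an alignment, esl-alipid convention.

    identity = 100 x (columns where both sequences carry the same non-gap
    residue) / min(non-gap residue count of a, non-gap residue count of b),
    optionally after trimming termini outside the profile reference span.
    """
    for name in (name_a, name_b):
        if name not in aln.sequences:
            raise KeyError(f"sequence {name!r} not in alignment")
    a = aln.sequences[name_a]
    b = aln.sequences[name_b]
    if trim_to_reference:
        ref_cols = [i for i, m in enumerate(aln.reference_mask) if m]
        if not ref_cols:
            raise ValueError("reference mask has no reference columns to trim to")
        lo, hi = ref_cols[0], ref_cols[-1] + 1
        a, b = a[lo:hi], b[lo:hi]
    na = sum(1 for c in a if c not in GAP_CHARS)
    nb = sum(1 for c in b if c not in GAP_CHARS)
    if min(na, nb) == 0:
        raise ValueError("sequence has no residues in the compared span")
    matches = sum(
        1
        for ca, cb in zip(a, b)
        if ca not in GAP_CHARS and cb not in GAP_CHARS and ca.upper() == cb.upper()
    )
    return 100.0 * matches / min(na, nb)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def identity_phenotype_correlation(
    identities: Mapping[str, float],
    phenotype: Mapping[str, float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman correlation between percent identity and a phenotype.

    Computed over the genes shared by both maps (>= 3 required), with
    average ranks for ties.  For n <= ``exact_max_n`` the two-sided p-value
    is exact: the fraction of the n! rank permutations whose |rho| reaches
    the observed one; larger n use the t approximation.
    """
    shared = sorted(set(identities) & set(phenotype))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared keys")
    x = np.array([identities[k] for k in shared], dtype=float)
    y = np.array([phenotype[k] for k in shared], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho = _spearman_rho(x, y)
    n = len(shared)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(sps.spearmanr(x, y)[1])
    return rho, p
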