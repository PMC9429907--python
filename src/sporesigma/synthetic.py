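"""Seeded synthetic-data generators for every pipeline stage.

Each generator emits data with the statistical structure the corresponding
analysis stage assumes — planted homology-hit margins, a planted
sporulation clade with a nested sigB subclade, MOI-dependent lysis of
logistic growth, two-population event clouds with doublets and low-scatter
noise, and DE tables with planted sporulation-gene enrichment — together
with a truth sidecar sufficient to score the stage without re-deriving
labels.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sigma_survey import DEFAULT_CATALOG, FamilyCatalog

__all__ = [
    "gen_hmm_hits",
    "gen_tree",
    "gen_growth_curves",
    "gen_flow_events",
    "gen_flow_pair",
    "gen_de_table",
]


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------


def gen_hmm_hits(
    n_proteins: int,
    catalog: FamilyCatalog = DEFAULT_CATALOG,
    evalue_margin: float = 10.0,
    general_hit_rate: float = 0.0,
    n_decoys: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hit tables with planted family labels and E-value margins.

    Each protein receives a hit to its planted (non-general) family with a
    sequence E-value log-uniform in [1e-40, 1e-10]; decoy hits to other
    non-general families are at least ``evalue_margin`` times larger; with
    probability ``general_hit_rate`` an umbrella-family hit smaller than
    all others is planted, exercising the fallback rule.

    Returns (hit_table, truth) where truth records the planted family and
    whether a general hit was planted best.
    """
    if evalue_margin <= 1:
        raise ValueError("evalue_margin must exceed 1")
    non_general = [f for f in catalog.families if not catalog.is_general(f)]
    general = sorted(catalog.general)
    if not non_general:
        raise ValueError("catalog has no non-general families to plant")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for i in range(n_proteins):
        pid = f"prot{i:05d}"
        planted = non_general[rng.integers(len(non_general))]
        log_e = rng.uniform(-40, -10)
        e_planted = 10.0**log_e
        rows.append((pid, planted, e_planted, -10.0 * log_e))
        decoy_pool = [f for f in non_general if f != planted]
        for fam in rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False):
            e_decoy = e_planted * evalue_margin * 10.0 ** rng.uniform(0, 3)
            rows.append((pid, fam, e_decoy, -10.0 * np.log10(e_decoy)))
        general_best = bool(general) and rng.uniform() < general_hit_rate
        if general_best:
            fam = general[rng.integers(len(general))]
            e_gen = e_planted / 10.0 ** rng.uniform(1, 3)
            rows.append((pid, fam, e_gen, -10.0 * np.log10(e_gen)))
        truth_rows.append((pid, planted, general_best))
    hits = pd.DataFrame(rows, columns=["protein_id", "family_id", "evalue", "score"])
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "planted_family", "general_best"])
    return hits, truth


# ---------------------------------------------------------------------------
# annotated trees
# ---------------------------------------------------------------------------


def _random_subtree(leaves: list[str], rng: np.random.Generator) -> str:
    """Random binary newick over pre-rendered leaf/subtree strings."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        bl, br = rng.uniform(0.05, 0.5, size=2)
        nodes.append(f"({left}:{bl:.4f},{right}:{br:.4f})")
    return nodes[0]


@dataclass(frozen=True)
class TreeTruth:
    member_phage_tips: frozenset[str]
    clade_phage_tips: frozenset[str]
    sigb_phage_tips: frozenset[str]
    outside_phage_tips: frozenset[str]


def gen_tree(
    n_phage_in_clade: int,
    n_phage_outside: int,
    spore_refs: Sequence[str] = ("sigF_ref", "sigG_ref", "sigE_ref", "sigK_ref"),
    sigb_refs: Sequence[str] = ("sigB_ref", "sigB_rel_ref"),
    n_phage_in_sigb: int = 0,
    seed: int = 0,
) -> tuple[str, pd.DataFrame, TreeTruth]:
    """Rooted tree with a planted sporulation clade and nested sigB subclade.

    The sporulation clade holds the sporulation reference tips, the planted
    phage members, and a nested sigB subclade (sigB references plus any
    phage tips planted there, which the exclusion rule must drop).  A
    sister clade holds out-of-clade phage tips and non-sporulation
    bacterial references; a bacterial outgroup roots the tree.

    Returns (newick, tip metadata, truth membership).
    """
    if min(n_phage_in_clade, n_phage_outside, n_phage_in_sigb) < 0:
        raise ValueError("tip counts must be non-negative")
    if not spore_refs or not sigb_refs:
        raise ValueError("reference tip sets must be non-empty")
    if n_phage_in_sigb > 0 and len(sigb_refs) < 2:
        # a single reference tip's MRCA is the leaf itself, so planted phage
        # tips in the subclade could never be excluded
        raise ValueError("planting phage tips in the sigB subclade needs >= 2 sigB references")
    rng = np.random.default_rng(seed)
    in_tips = [f"phageIN{i:03d}" for i in range(n_phage_in_clade)]
    out_tips = [f"phageOUT{i:03d}" for i in range(n_phage_outside)]
    sigb_phage = [f"phageSIGB{i:03d}" for i in range(n_phage_in_sigb)]
    other_refs = ["sigA_ref", "ecf_ref"]
    outgroup = "outgroup_ref"

    # sigB subclade: first sigB reference sits at its root so the references'
    # MRCA spans exactly this subtree
    sigb_rest = list(sigb_refs[1:]) + sigb_phage
    if sigb_rest:
        sub = _random_subtree(sigb_rest, rng)
        sigb_clade = f"({sigb_refs[0]}:{rng.uniform(0.05, 0.5):.4f},{sub}:{rng.uniform(0.05, 0.5):.4f})"
    else:
        sigb_clade = str(sigb_refs[0])
    # sporulation clade: one sporulation reference at the root; the rest,
    # the planted members and the sigB subclade below it
    spore_rest = list(spore_refs[1:]) + in_tips + [sigb_clade]
    sub = _random_subtree(spore_rest, rng)
    spore_clade = f"({spore_refs[0]}:{rng.uniform(0.05, 0.5):.4f},{sub}:{rng.uniform(0.05, 0.5):.4f})"
    sister = _random_subtree(out_tips + other_refs, rng)
    newick = (
        f"({outgroup}:{rng.uniform(0.05, 0.5):.4f},"
        f"({spore_clade}:{rng.uniform(0.05, 0.5):.4f},{sister}:{rng.uniform(0.05, 0.5):.4f})"
        f":{rng.uniform(0.05, 0.5):.4f});"
    )

    meta_rows = []
    for t in in_tips + out_tips + sigb_phage:
        meta_rows.append((t, "phage", ""))
    for t in spore_refs:
        meta_rows.append((t, "bacterial", "sporulation"))
    for t in sigb_refs:
        meta_rows.append((t, "bacterial", "sigB"))
    for t, fam in zip(other_refs + [outgroup], ["sigA", "ECF", "outgroup"]):
        meta_rows.append((t, "bacterial", fam))
    metadata = pd.DataFrame(meta_rows, columns=["tip", "source", "family"])
    truth = TreeTruth(
        member_phage_tips=frozenset(in_tips),
        clade_phage_tips=frozenset(in_tips + sigb_phage),
        sigb_phage_tips=frozenset(sigb_phage),
        outside_phage_tips=frozenset(out_tips),
    )
    return newick, metadata, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def gen_growth_curves(
    mois: Sequence[float] = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0),
    lysis_strength: float = 1.0,
    r: float = 1.4,
    K: float = 1.2,
    od0: float = 0.05,
    onset0: float = 3.0,
    onset_slope: float = 0.75,
    noise_sd: float = 0.01,
    n_replicates: int = 8,
    t_max: float = 16.0,
    dt: float = 0.25,
    strain: str = "WT",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logistic growth curves with MOI-dependent lysis.

    The uninfected control follows logistic growth dN/dt = rN(1 - N/K) from
    ``od0``; infected wells multiply the control by exp(-theta (t - t_on))
    after an onset t_on that decreases with log10(MOI) (earlier lysis at
    higher phage load), theta = ``lysis_strength``.  Gaussian measurement
    noise (sd ``noise_sd``) is added and floored at 0.  Defaults follow a
    16-h plate read at 15-min intervals with an 8-replicate dilution
    series.

    Returns (long-format plate table, noise-free truth table).
    """
    if K <= 0 or r <= 0:
        raise ValueError("r and K must be positive")
    if 0.0 not in mois:
        raise ValueError("MOI series must include the MOI=0 control")
    if lysis_strength < 0 or noise_sd < 0:
        raise ValueError("lysis_strength and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    control = K / (1.0 + (K / od0 - 1.0) * np.exp(-r * t))
    nonzero = sorted(m for m in mois if m > 0)
    moi_ref = nonzero[0] if nonzero else 1.0

    rows = []
    truth_rows = []
    for rep in range(n_replicates):
        rep_id = f"r{rep + 1}"
        for moi in mois:
            if moi == 0:
                clean = control
            else:
                t_on = max(0.0, onset0 - onset_slope * np.log10(moi / moi_ref))
                decay = np.exp(-lysis_strength * np.clip(t - t_on, 0.0, None))
                clean = control * decay
            noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=t.size), 0.0, None)
            well = f"{rep_id}@moi{moi:g}"
            for ti, cv, nv in zip(t, clean, noisy):
                rows.append((well, strain, moi, rep_id, ti, nv))
                truth_rows.append((well, strain, moi, rep_id, ti, cv))
    cols = ["well", "strain", "moi", "replicate", "time_h", "od600"]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(truth_rows, columns=cols)


# ---------------------------------------------------------------------------
# flow-cytometry event clouds
# ---------------------------------------------------------------------------

#: Component means on the asinh scale: spores exclude the SYBR green stain
#: (dim fluorescence); vegetative cells stain brightly and scatter slightly
#: larger.
SPORE_MEAN = (4.0, 2.5)
VEG_MEAN = (4.6, 7.5)
COMPONENT_SD = 0.35


def gen_flow_events(
    n_events: int,
    spore_fraction: float,
    doublet_fraction: float = 0.05,
    noise_fraction: float = 0.05,
    cofactor: float = 1.0,
    sample_id: str = "S1",
    strain: str = "ev",
    run: str = "run1",
    treatment: str = "control",
    pair_id: str = "p1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-population event cloud with doublets and low-scatter noise.

    Cells are Gaussian on the asinh scale around the spore and vegetative
    component means; raw intensities are the sinh back-transform.  Singlet
    FSC height tracks FSC area along a line with bounded jitter; doublets
    double the raw areas (scatter and fluorescence) while keeping singlet
    height; noise events sit at low scatter.  Fractions are of total
    events.

    Returns (raw event table with sample metadata, truth labels).
    """
    if not (0 < spore_fraction < 1):
        raise ValueError("spore_fraction must lie in (0, 1)")
    if doublet_fraction + noise_fraction >= 1:
        raise ValueError("doublet + noise fractions must leave room for cells")
    rng = np.random.default_rng(seed)
    n_doublet = int(round(n_events * doublet_fraction))
    n_noise = int(round(n_events * noise_fraction))
    n_cells = n_events - n_doublet - n_noise

    def _cells(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        is_spore = rng.uniform(size=n) < spore_fraction
        mean = np.where(is_spore[:, None], SPORE_MEAN, VEG_MEAN)
        fsc_a_t = rng.normal(mean[:, 0], COMPONENT_SD)
        fl_a_t = rng.normal(mean[:, 1], COMPONENT_SD)
        return fsc_a_t, fl_a_t, is_spore

    # singlets
    a_t, fl_t, is_spore = _cells(n_cells)
    h_t = 0.98 * a_t + rng.uniform(-0.05, 0.05, size=n_cells)
    raw_a = np.sinh(a_t) * cofactor
    raw_h = np.sinh(h_t) * cofactor
    raw_fl = np.sinh(fl_t) * cofactor
    labels = np.where(is_spore, "spore", "vegetative")

    # doublets: two coincident cells — raw areas double, height stays
    da_t, dfl_t, _ = _cells(n_doublet)
    dh_t = 0.98 * da_t + rng.uniform(-0.05, 0.05, size=n_doublet)
    d_raw_a = 2.0 * np.sinh(da_t) * cofactor
    d_raw_h = np.sinh(dh_t) * cofactor
    d_raw_fl = 2.0 * np.sinh(dfl_t) * cofactor

    # low-scatter noise (debris, not cells)
    na_t = rng.normal(1.0, 0.3, size=n_noise)
    nh_t = 0.98 * na_t + rng.uniform(-0.05, 0.05, size=n_noise)
    nfl_t = rng.normal(0.5, 0.3, size=n_noise)
    n_raw_a = np.sinh(na_t) * cofactor
    n_raw_h = np.sinh(nh_t) * cofactor
    n_raw_fl = np.sinh(np.abs(nfl_t)) * cofactor

    fsc_a = np.concatenate([raw_a, d_raw_a, n_raw_a])
    fsc_h = np.concatenate([raw_h, d_raw_h, n_raw_h])
    fl_a = np.concatenate([raw_fl, d_raw_fl, n_raw_fl])
    label = np.concatenate([labels, np.full(n_doublet, "doublet"), np.full(n_noise, "noise")])
    order = rng.permutation(n_events)

    events = pd.DataFrame(
        {
            "sample_id": sample_id,
            "strain": strain,
            "run": run,
            "treatment": treatment,
            "pair_id": pair_id,
            "fsc_h": fsc_h[order],
            "fsc_a": fsc_a[order],
            "fl_a": fl_a[order],
        }
    )
    truth = pd.DataFrame({"sample_id": sample_id, "label": label[order]})
    return events, truth


def gen_flow_pair(
    n_events: int,
    f_induced: float,
    f_control: float,
    strain: str = "ev",
    run: str = "run1",
    pair_id: str = "p1",
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired induced/control samples with planted spore fractions.

    Returns the concatenated event table and truth labels; the planted
    spore yield is f_induced / f_control.
    """
    ind, ind_truth = gen_flow_events(
        n_events,
        f_induced,
        sample_id=f"{pair_id}-induced",
        strain=strain,
        run=run,
        treatment="induced",
        pair_id=pair_id,
        seed=seed,
        **kwargs,
    )
    ctl, ctl_truth = gen_flow_events(
        n_events,
        f_control,
        sample_id=f"{pair_id}-control",
        strain=strain,
        run=run,
        treatment="control",
        pair_id=pair_id,
        seed=seed + 1,
        **kwargs,
    )
    return (
        pd.concat([ind, ctl], ignore_index=True),
        pd.concat([ind_truth, ctl_truth], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


def gen_de_table(
    n_genes: int = 4000,
    n_sporulation: int = 500,
    background_up_prob: float = 0.05,
    sporulation_up_prob: float = 0.6,
    down_prob: float = 0.05,
    seed: int = 0,
    base: pd.DataFrame | None = None,
    resample_noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE tables with planted sporulation-gene enrichment.

    Sporulation genes go up with probability ``sporulation_up_prob``,
    background genes with ``background_up_prob``; any gene goes down with
    ``down_prob``.  Up genes draw log2fc > 1 and p_adj < 0.05, down genes
    symmetrically, null genes log2fc near 0 with uniform p_adj.

    Passing a previous truth table as ``base`` re-uses its class draws and
    baseline effect sizes (plus fresh noise of sd ``resample_noise_sd``),
    emulating a second induction strain with the same underlying response.

    Returns (table, truth) where truth records the class draw and the
    baseline log2fc per gene.
    """
    if not (0 <= background_up_prob <= 1 and 0 <= sporulation_up_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_sporulation > n_genes:
        raise ValueError("n_sporulation cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)])
    is_spor = np.zeros(n_genes, dtype=bool)
    is_spor[:n_sporulation] = True

    if base is not None:
        classes = base["class"].to_numpy()
        base_lfc = base["base_log2fc"].to_numpy()
        lfc = base_lfc + rng.normal(0.0, resample_noise_sd, size=n_genes)
    else:
        up_p = np.where(is_spor, sporulation_up_prob, background_up_prob)
        u = rng.uniform(size=n_genes)
        classes = np.where(u < up_p, "up", np.where(u < up_p + down_prob, "down", "null"))
        base_lfc = np.where(
            classes == "up",
            rng.uniform(1.2, 4.0, size=n_genes),
            np.where(
                classes == "down",
                -rng.uniform(1.2, 4.0, size=n_genes),
                rng.normal(0.0, 0.3, size=n_genes),
            ),
        )
        lfc = base_lfc
    p_adj = np.where(
        classes == "null",
        rng.uniform(size=n_genes),
        rng.uniform(1e-8, 0.04, size=n_genes),
    )
    table = pd.DataFrame(
        {"gene_id": genes, "log2fc": lfc, "p_adj": p_adj, "is_sporulation": is_spor}
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "class": classes, "base_log2fc": base_lfc, "is_sporulation": is_spor}
    )
    return table, truth
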