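"""Seeded synthetic 16S cohorts with the structure the analysis assumes.

The generative model is logistic-normal / multinomial: per-taxon latent
log-abundances are Gaussian, group severity and batch shift them additively
on the log scale, the softmax closes them to proportions, and sequencing
draws multinomial counts at a Poisson depth.  Planted log-scale effects
therefore map directly onto clr expectations, which keeps recovery tests
close to analytic.  HLA-by-taxon interactions are planted on the *outcome*
side (disease state re-drawn from a logistic model with a clr x carrier
product term), matching the direction of the interaction regressions;
antibody titers are drawn from a per-group linear model in the clr of the
interacting taxa.  Healthy controls get missing HLA and titers, as in a
cohort where genotyping and serology cover only the anti-Ro positive women.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    HLA_COLUMNS,
    RANKS,
    TITER_COLUMNS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
)
from .transforms import build_tree_from_taxonomy


@dataclass
class SyntheticCohortSpec:
    """All knobs of the generative model.  Defaults emulate the study
    cohort: 23 healthy controls, 43 Asym/UAS and 82 SS/SLE mothers, ~200
    species in a 6-level bacterial taxonomy, ~32k reads/sample."""

    n_per_group: tuple[int, int, int] = (23, 43, 82)
    n_taxa_species: int = 200
    #: total number of units per rank (phylum..genus); species count is
    #: n_taxa_species.  Scaled-down version of a real 16S survey's richness.
    taxonomy_shape: dict = field(
        default_factory=lambda: {
            "phylum": 8, "class": 14, "order": 24, "family": 40, "genus": 150,
        }
    )
    base_logmean: float = 0.0
    base_logsd: float = 2.0
    seq_depth_mean: float = 32000.0
    n_batches: int = 3
    batch_effect_sd: float = 0.25
    #: per-sample log-abundance noise around the group/batch means
    sample_noise_sd: float = 1.0
    #: genus-level monotone severity effects: (genus, delta per step, sign)
    planted_ordinal: list = field(default_factory=list)
    #: genus-level non-monotone effects: (genus, (off_HC, off_Asym, off_SS))
    planted_nonmonotone: list = field(default_factory=list)
    hla_carrier_freq: dict = field(
        default_factory=lambda: dict(zip(HLA_COLUMNS, (0.20, 0.20, 0.25, 0.20)))
    )
    #: (genus, allele, interaction log-OR per clr unit)
    planted_hla_interaction: list = field(default_factory=list)
    #: titer -> dict(intercept, group_effect, noise_sd,
    #:               interactions=[(genus, slope_asym, slope_ss)])
    titer_model: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, genus_names: list[str] | None = None) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs >= 2 samples")
        shape = self.taxonomy_shape
        totals = [1] + [shape[r] for r in RANKS[1:-1]] + [self.n_taxa_species]
        for a, b, rank in zip(totals, totals[1:], RANKS[1:]):
            if b < a:
                raise ValueError(
                    f"taxonomy_shape: {rank} count {b} < parent rank count {a}"
                )
        for f in self.hla_carrier_freq.values():
            if not 0 <= f <= 1:
                raise ValueError("carrier frequencies must lie in [0, 1]")
        if genus_names is not None:
            known = set(genus_names)
            for g, *_ in (
                list(self.planted_ordinal)
                + list(self.planted_nonmonotone)
                + list(self.planted_hla_interaction)
            ):
                if g not in known:
                    raise ValueError(f"planted taxon {g!r} not in taxonomy")
            for tm in self.titer_model.values():
                for g, *_ in tm.get("interactions", []):
                    if g not in known:
                        raise ValueError(f"planted taxon {g!r} not in taxonomy")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    planted_ordinal: list
    planted_nonmonotone: list
    planted_hla_interaction: list
    titer_model: dict
    latent_log_abundance: pd.DataFrame  # samples x leaf taxa
    genus_of_taxon: pd.Series


def _build_taxonomy(spec: SyntheticCohortSpec, rng: np.random.Generator) -> TaxonomyTable:
    """Nest each rank's units randomly inside the rank above (every parent
    gets at least one child)."""
    shape = spec.taxonomy_shape
    counts = {r: shape[r] for r in RANKS[1:-1]}
    counts["species"] = spec.n_taxa_species
    units: dict[str, list[str]] = {"kingdom": ["Bacteria"]}
    parent_of: dict[str, dict[str, str]] = {}
    prefix = {"phylum": "P", "class": "C", "order": "O", "family": "F",
              "genus": "G", "species": "S"}
    prev = "kingdom"
    for rank in RANKS[1:]:
        n = counts[rank]
        names = [f"{prefix[rank]}{i + 1:03d}" for i in range(n)]
        parents = units[prev]
        assign = list(np.arange(len(parents)))  # one child per parent first
        extra = rng.integers(0, len(parents), size=n - len(parents))
        assign = np.array(assign + list(extra))
        rng.shuffle(assign)
        parent_of[rank] = {nm: parents[a] for nm, a in zip(names, assign)}
        units[rank] = names
        prev = rank
    rows = []
    for sp in units["species"]:
        lineage = {"species": sp}
        child = sp
        for rank in reversed(RANKS[:-1]):
            child = parent_of[RANKS[RANKS.index(rank) + 1]][child]
            lineage[rank] = child
        rows.append([lineage[r] for r in RANKS])
    taxon_ids = [f"t_{sp}" for sp in units["species"]]
    df = pd.DataFrame(rows, columns=list(RANKS), index=taxon_ids)
    return TaxonomyTable(df)


def generate(spec: SyntheticCohortSpec):
    """Draw one cohort.

    Returns ``(CountTable, TaxonomyTable, SampleMetadata, TaxonTree,
    SyntheticTruth)``.  Same spec + seed gives bit-identical outputs;
    per-stage RNG streams are spawned from the seed so adding a planted
    effect does not perturb unrelated draws.
    """
    ss = np.random.SeedSequence(spec.seed)
    (r_tax, r_base, r_noise, r_batch, r_depth, r_counts,
     r_hla, r_titer, r_tree) = [np.random.default_rng(s) for s in ss.spawn(9)]

    tax = _build_taxonomy(spec, r_tax)
    spec.validate(genus_names=list(tax.data["genus"].unique()))
    taxa = list(tax.data.index)
    genus_of = tax.data["genus"]
    n_taxa = len(taxa)

    n_hc, n_asym, n_ss = spec.n_per_group
    n = n_hc + n_asym + n_ss
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    group = np.array(
        ["HC"] * n_hc + ["ASYM_UAS"] * n_asym + ["SS_SLE"] * n_ss
    )
    score = np.where(group == "HC", -1.0, np.where(group == "ASYM_UAS", 0.0, 1.0))
    batch = np.array([f"b{(i % spec.n_batches) + 1}" for i in range(n)])

    base = r_base.normal(spec.base_logmean, spec.base_logsd, size=n_taxa)
    eta = np.tile(base, (n, 1))
    eta += r_noise.normal(0.0, spec.sample_noise_sd, size=(n, n_taxa))
    batch_off = r_batch.normal(0.0, spec.batch_effect_sd,
                               size=(spec.n_batches, n_taxa))
    batch_idx = np.array([int(b[1:]) - 1 for b in batch])
    eta += batch_off[batch_idx]

    members = {g: np.flatnonzero(genus_of.to_numpy() == g)
               for g in genus_of.unique()}

    genus_order = list(pd.unique(genus_of))
    genus_col = {g: j for j, g in enumerate(genus_order)}
    agg = np.zeros((n_taxa, len(genus_order)))
    for g, idx in (
        (g, np.flatnonzero(genus_of.to_numpy() == g)) for g in genus_order
    ):
        agg[idx, genus_col[g]] = 1.0

    def _genus_clr(e: np.ndarray) -> np.ndarray:
        """Latent genus-level clr: the covariate the interaction models fit."""
        p = np.exp(e - e.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        pg = p @ agg
        lpg = np.log(pg)
        return lpg - lpg.mean(axis=1, keepdims=True)

    # HLA carriers for anti-Ro mothers; HC missing
    is_ro = group != "HC"
    hla = pd.DataFrame(np.nan, index=sample_ids, columns=list(HLA_COLUMNS))
    for allele in HLA_COLUMNS:
        draws = (r_hla.random(n) < spec.hla_carrier_freq[allele]).astype(float)
        hla.loc[is_ro, allele] = draws[is_ro]

    # planted HLA interactions re-draw disease state among anti-Ro mothers
    # from a logistic model in baseline clr x carrier, *before* the severity
    # effects are planted, so the ordinal structure refers to final groups
    if spec.planted_hla_interaction:
        clr0 = _genus_clr(eta)
        base_logit = np.log(n_ss / n_asym)  # keep expected group balance
        lin = np.full(n, base_logit)
        for genus, allele, log_or in spec.planted_hla_interaction:
            gclr = clr0[:, genus_col[genus]]
            gclr = gclr - gclr[is_ro].mean()  # centering only shifts the
            carrier = hla[allele].to_numpy()  # carrier main effect
            lin += np.where(is_ro, log_or * gclr * np.nan_to_num(carrier), 0.0)
        p_ss = 1 / (1 + np.exp(-lin))
        redraw = r_hla.random(n) < p_ss
        group = np.where(is_ro, np.where(redraw, "SS_SLE", "ASYM_UAS"), group)
        score = np.where(group == "HC", -1.0,
                         np.where(group == "ASYM_UAS", 0.0, 1.0))

    for genus, delta, sign in spec.planted_ordinal:
        eta[:, members[genus]] += (sign * delta * score)[:, None]
    for genus, pattern in spec.planted_nonmonotone:
        offs = dict(zip(GROUPS, pattern))
        per_sample = np.array([offs[g] for g in group])
        eta[:, members[genus]] += per_sample[:, None]

    props = np.exp(eta - eta.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    latent_genus_clr = _genus_clr(eta)

    depth = r_depth.poisson(spec.seq_depth_mean, size=n)
    counts = np.vstack(
        [r_counts.multinomial(depth[i], props[i]) for i in range(n)]
    )

    # titers from the per-group linear model; HC missing
    titers = pd.DataFrame(np.nan, index=sample_ids, columns=list(TITER_COLUMNS))
    is_ss = group == "SS_SLE"
    for titer in TITER_COLUMNS:
        tm = spec.titer_model.get(titer)
        if tm is None:
            # uninformative positive titer for anti-Ro mothers
            vals = r_titer.normal(10.0, 1.0, size=n)
        else:
            vals = np.full(n, float(tm.get("intercept", 10.0)))
            vals += float(tm.get("group_effect", 0.0)) * is_ss
            for genus, sl_asym, sl_ss in tm.get("interactions", []):
                gclr = latent_genus_clr[:, genus_col[genus]]
                vals += np.where(is_ss, sl_ss, sl_asym) * gclr
            vals += r_titer.normal(0.0, float(tm.get("noise_sd", 1.0)), size=n)
        titers.loc[is_ro, titer] = np.maximum(vals, 0.0)[is_ro]

    ct = CountTable(pd.DataFrame(counts, index=sample_ids, columns=taxa))
    md_df = pd.DataFrame({"group": group, "batch": batch}, index=sample_ids)
    md_df = pd.concat([md_df, hla, titers], axis=1)
    md = SampleMetadata(md_df)
    tree = build_tree_from_taxonomy(tax, seed=int(r_tree.integers(2**31)))
    truth = SyntheticTruth(
        planted_ordinal=list(spec.planted_ordinal),
        planted_nonmonotone=list(spec.planted_nonmonotone),
        planted_hla_interaction=list(spec.planted_hla_interaction),
        titer_model=dict(spec.titer_model),
        latent_log_abundance=pd.DataFrame(eta, index=sample_ids, columns=taxa),
        genus_of_taxon=genus_of,
    )
    return ct, tax, md, tree, truth


def default_paper_like_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Cohort emulating the study: groups (23, 43, 82), ~150 genera / 200
    species, depth 32k, 13 monotone severity genera, 2 HLA interactions and
    4 anti-Ro52 IgA titer interactions."""
    n_planted = 13
    planted = [
        (f"G{i + 1:03d}", 1.0, 1 if i % 2 == 0 else -1) for i in range(n_planted)
    ]
    hla_planted = [
        ("G001", "hla_drb1_0301", 0.5),
        ("G003", "hla_dqb1_0602", 0.5),
    ]
    titer = {
        "ro52_iga": {
            "intercept": 10.0,
            "group_effect": 0.0,
            "noise_sd": 1.0,
            "interactions": [
                ("G002", -1.0, 0.0),
                ("G004", 0.0, -1.0),
                ("G005", -1.0, 0.0),
                ("G006", 1.0, 0.0),
            ],
        }
    }
    return SyntheticCohortSpec(
        planted_ordinal=planted,
        planted_hla_interaction=hla_planted,
        titer_model=titer,
        seed=seed,
    )
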