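"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three input families:

* paired tumor/normal read-count tables with a planted shared first-hit
  mutation, per-patient secondary mutations in a disease module, and
  passenger sites each designed to fail exactly one filtration criterion;
* a factor-model expression matrix with block-correlated gene modules, one
  of which is shifted downward in tumor samples;
* a small GO-like term structure with one term concentrated in the disease
  module and a parent term that strictly contains it.

Everything is driven by one :class:`SimulationPlan` and a seed, and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .coexpression import GREY, ExpressionDataset
from .variants import (
    POPFREQ_DBS,
    AnnotatedVariant,
    VariantCandidate,
    annotate_calls,
    call_somatic,
)

#: Sequencing error rate used for normal-tissue alt reads.
NORMAL_ERROR_RATE = 0.002

#: Site fates recorded in the truth table and the cascade stages each implies.
FATE_STAGES = {
    "final_first_hit": {"QC", "P", "S", "F"},
    "final_secondary": {"QC", "P", "S", "F"},
    "final_background": {"QC", "P", "S", "F"},
    "fail_qc_depth": set(),
    "fail_qc_normal_vaf": set(),
    "fail_common": {"QC", "S"},
    "fail_benign": {"QC", "P"},
    "synonymous": set(),
}


class PlanError(ValueError):
    pass


@dataclass
class SimulationPlan:
    """The stated world every synthetic dataset is drawn from.

    Variant side: 4 patients, a shared clonal first hit at VAF 0.35, later
    subclonal secondaries at VAF in [0.05, 0.25], mean sequencing depth 150
    (deep targeted-exome territory, where binomial VAF noise cannot blur
    the planted ordering).  Expression side: 300 genes, three modules of 60
    genes at loading 0.9 over noise of SD 0.1 (within-module correlations
    near 0.99, the tight-module regime a static dendrogram cut at 0.4
    presumes), 6 normal + 6 tumor samples; the disease module's
    factor mean drops by 5 SD in tumor samples, chosen to emulate the
    profound down-regulation (module-trait r ~ 0.93) the analysis is built
    to detect.
    """

    n_patients: int = 4
    n_sites_per_patient: int = 12
    first_hit_vaf: float = 0.35
    secondary_vaf_range: tuple[float, float] = (0.05, 0.25)
    mean_depth: int = 150
    n_genes: int = 300
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (60, 60, 60)
    loading: float = 0.9
    noise_sd: float = 0.1
    n_normal_samples: int = 6
    n_tumor_samples: int = 6
    tumor_shift: float = -5.0
    n_secondary_per_patient: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.secondary_vaf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise PlanError("secondary_vaf_range must be ordered within [0,1]")
        if self.first_hit_vaf <= hi:
            raise PlanError(
                "first_hit_vaf must exceed max(secondary_vaf_range) so the "
                "planted ordering is recoverable"
            )
        if sum(self.module_sizes) > self.n_genes:
            raise PlanError("sum(module_sizes) exceeds n_genes")
        if len(self.module_sizes) != self.n_modules:
            raise PlanError("module_sizes length must equal n_modules")
        if self.mean_depth < 30:
            raise PlanError(
                "mean_depth too low to realize the VAF categories distinctly"
            )
        if self.n_sites_per_patient < 9:
            raise PlanError(
                "need >= 9 sites per patient (first hit, secondaries, five "
                "single-filter failures, one synonymous)"
            )
        if self.n_patients < 1:
            raise PlanError("need at least one patient")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def module_labels(self) -> dict[str, str]:
        """Planted gene -> module map; M1 is the disease module."""
        labels: dict[str, str] = {}
        ids = self.gene_ids
        start = 0
        for m, size in enumerate(self.module_sizes, start=1):
            for g in ids[start : start + size]:
                labels[g] = f"M{m}"
            start += size
        for g in ids[start:]:
            labels[g] = GREY
        return labels

    @property
    def hub_gene(self) -> str:
        """The designated first-hit gene (first gene of the disease module)."""
        return self.gene_ids[0]

    @property
    def disease_module(self) -> str:
        return "M1"


def _benign_annotation() -> dict:
    return {
        "cadd_phred": 8.0,
        "sift_damaging": False,
        "polyphen_damaging": False,
    }


def _damaging_annotation() -> dict:
    return {
        "cadd_phred": 32.0,
        "sift_damaging": True,
        "polyphen_damaging": True,
    }


def _draw_depth(rng: np.random.Generator, mean_depth: int, floor: int) -> int:
    d = int(rng.poisson(mean_depth))
    return max(d, floor)


def _draw_pass_counts(
    rng: np.random.Generator,
    vaf: float,
    mean_depth: int,
    cfg: PipelineConfig,
    max_tries: int = 1000,
) -> tuple[int, int, int, int]:
    """Binomial read counts conditioned on passing the QC gate.

    Tumor alt ~ Binomial(depth, vaf); normal alt ~ Binomial(depth, error
    rate).  Draws are rejected until every QC criterion holds, so a site
    whose intended fate is to survive QC really does — the conditioning is
    mild at the default depth (acceptance probability near 1).
    """
    from .variants import SomaticCall, apply_qc, fisher_p_values

    floor = cfg.qc_depth_min + 5
    for _ in range(max_tries):
        nd = _draw_depth(rng, mean_depth, floor)
        td = _draw_depth(rng, mean_depth, floor)
        na = int(rng.binomial(nd, NORMAL_ERROR_RATE))
        ta = int(rng.binomial(td, vaf))
        nr, tr = nd - na, td - ta
        p = float(
            fisher_p_values(
                np.array([nr]), np.array([na]), np.array([tr]), np.array([ta])
            )[0]
        )
        call = SomaticCall(
            candidate=VariantCandidate("x", "chr1", 1, "A", "T", nr, na, tr, ta),
            fisher_p=p,
            normal_vaf=na / nd,
            tumor_vaf=ta / td,
            qc_pass=False,
        )
        if apply_qc(call, cfg):
            return nr, na, tr, ta
    raise PlanError(
        f"could not realize a QC-passing site at VAF {vaf} and mean depth "
        f"{mean_depth}; increase mean_depth"
    )


def simulate_variants(
    plan: SimulationPlan, cfg: PipelineConfig | None = None
) -> tuple[list[VariantCandidate], pd.DataFrame, pd.DataFrame]:
    """Generate candidates, their annotation table and the truth table.

    Per patient: one shared first-hit site in the hub gene (identical
    chrom/pos/ref/alt across patients, tumor VAF ``first_hit_vaf``),
    ``n_secondary_per_patient`` secondary sites in disease-module genes at
    VAFs from ``secondary_vaf_range``, five passenger sites each failing
    exactly one named filter (low depth, high normal VAF, common allele,
    benign predictions, synonymous consequence), and background final
    mutations filling up to ``n_sites_per_patient``.

    The truth table records each site's intended fate; by construction the
    filtration cascade reproduces those fates exactly.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(plan.seed)
    labels = plan.module_labels()
    module_genes = [
        g for g in plan.gene_ids
        if labels[g] == plan.disease_module and g != plan.hub_gene
    ]
    background_genes = [g for g in plan.gene_ids if labels[g] == GREY]
    if len(module_genes) < plan.n_secondary_per_patient:
        raise PlanError("disease module too small for the secondary sites")

    # 1 first hit + secondaries + 5 planted single-filter failures; the rest
    # are background finals
    n_fillers = plan.n_sites_per_patient - 1 - plan.n_secondary_per_patient - 5
    if n_fillers < 0:
        raise PlanError(
            "n_sites_per_patient too small for the planted site composition"
        )

    candidates: list[VariantCandidate] = []
    ann_rows: dict[tuple, dict] = {}
    truth_rows: list[dict] = []
    patients = [f"P{i + 1}" for i in range(plan.n_patients)]

    # distinct genomic coordinates per planted site; the shared first hit
    # reuses one fixed site across patients
    first_site = ("chr7", 140_453_136, "A", "T")
    next_pos = {"chr1": 1_000_000}

    def new_site(chrom: str = "chr1") -> tuple[str, int, str, str]:
        pos = next_pos.get(chrom, 1_000_000)
        next_pos[chrom] = pos + 997
        ref, alt = "C", "G"
        return (chrom, pos, ref, alt)

    def add(
        pid: str,
        site: tuple,
        gene: str,
        fate: str,
        counts: tuple[int, int, int, int],
        consequence: str,
        popfreq: Mapping[str, float | None],
        predictions: Mapping[str, object],
    ) -> None:
        chrom, pos, ref, alt = site
        nr, na, tr, ta = counts
        candidates.append(
            VariantCandidate(pid, chrom, pos, ref, alt, nr, na, tr, ta)
        )
        key = (chrom, pos, ref, alt)
        row = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": gene, "consequence": consequence,
            **{db: popfreq.get(db) for db in POPFREQ_DBS},
            **predictions,
        }
        if key in ann_rows and ann_rows[key]["gene"] != gene:
            raise PlanError("site reused across genes")
        ann_rows[key] = row
        truth_rows.append(
            {
                "patient_id": pid, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "gene": gene, "fate": fate,
            }
        )

    never_seen = {db: None for db in POPFREQ_DBS}
    rare_freqs = {db: 0.001 for db in POPFREQ_DBS}
    common_freqs = {db: 0.05 for db in POPFREQ_DBS}

    for pid in patients:
        # (i) shared first hit: damaging missense, never observed in EAS
        counts = _draw_pass_counts(rng, plan.first_hit_vaf, plan.mean_depth, cfg)
        add(pid, first_site, plan.hub_gene, "final_first_hit", counts,
            "missense", never_seen, _damaging_annotation())

        # (ii) secondary hits in disease-module genes, below first-hit VAF
        sec_genes = rng.choice(
            module_genes, size=plan.n_secondary_per_patient, replace=False
        )
        for g in sec_genes:
            vaf = float(rng.uniform(*plan.secondary_vaf_range))
            counts = _draw_pass_counts(rng, vaf, plan.mean_depth, cfg)
            add(pid, new_site(), str(g), "final_secondary", counts,
                "missense", rare_freqs, _damaging_annotation())

        # (iii) background final mutations (rare+severe, outside the module)
        fill_genes = rng.choice(
            background_genes, size=n_fillers, replace=False
        )
        for g in fill_genes:
            vaf = float(rng.uniform(*plan.secondary_vaf_range))
            counts = _draw_pass_counts(rng, vaf, plan.mean_depth, cfg)
            add(pid, new_site(), str(g), "final_background", counts,
                "stopgain", never_seen,
                {"cadd_phred": None, "sift_damaging": None,
                 "polyphen_damaging": None})

        # (iv) passengers failing exactly one named criterion each
        g_depth, g_nvaf, g_common, g_benign, g_syn = rng.choice(
            background_genes, size=5, replace=False
        )
        # low depth: normal depth one read short, everything else passing
        td = _draw_depth(rng, plan.mean_depth, cfg.qc_depth_min + 5)
        ta = max(int(rng.binomial(td, 0.3)), cfg.qc_tumor_alt_min)
        add(pid, new_site(), str(g_depth), "fail_qc_depth",
            (cfg.qc_depth_min - 1, 0, td - ta, ta),
            "missense", rare_freqs, _damaging_annotation())
        # high normal VAF: one normal alt read at depth 20 -> VAF 0.05
        td = _draw_depth(rng, plan.mean_depth, cfg.qc_depth_min + 5)
        ta = max(int(rng.binomial(td, 0.3)), cfg.qc_tumor_alt_min)
        add(pid, new_site(), str(g_nvaf), "fail_qc_normal_vaf",
            (19, 1, td - ta, ta),
            "missense", rare_freqs, _damaging_annotation())
        # common allele: QC-passing, severe, but frequent in all databases
        counts = _draw_pass_counts(rng, 0.3, plan.mean_depth, cfg)
        add(pid, new_site(), str(g_common), "fail_common", counts,
            "missense", common_freqs, _damaging_annotation())
        # benign: QC-passing, rare, but no tool calls it damaging
        counts = _draw_pass_counts(rng, 0.3, plan.mean_depth, cfg)
        add(pid, new_site(), str(g_benign), "fail_benign", counts,
            "missense", never_seen, _benign_annotation())
        # synonymous: discarded before filtration regardless of reads
        counts = _draw_pass_counts(rng, 0.3, plan.mean_depth, cfg)
        add(pid, new_site(), str(g_syn), "synonymous", counts,
            "synonymous", never_seen, _benign_annotation())

    annotation = pd.DataFrame(list(ann_rows.values()))
    truth = pd.DataFrame(truth_rows)
    return candidates, annotation, truth


def annotate_simulated(
    candidates: list[VariantCandidate],
    annotation: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> list[AnnotatedVariant]:
    """Convenience: somatic calling + annotation join in one step."""
    cfg = cfg or PipelineConfig()
    return annotate_calls(call_somatic(candidates, cfg), annotation, cfg)


def simulate_expression(
    plan: SimulationPlan,
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Factor-model expression matrix with planted modules.

    x_gs = loading * f_{m(g),s} + noise_sd * eps_gs for module genes, pure
    unit-variance noise for background genes.  Module factors are standard
    normal per sample and independent between modules; the disease module's
    factor mean is shifted by ``tumor_shift`` in tumor samples.  Returns
    the dataset and the planted gene -> module labels.
    """
    n_samples = plan.n_normal_samples + plan.n_tumor_samples
    if n_samples < 4:
        raise PlanError("need >= 4 samples for correlation to be defined")
    rng = np.random.default_rng(plan.seed + 1)
    labels = plan.module_labels()
    sample_ids = [f"N{i + 1}" for i in range(plan.n_normal_samples)] + [
        f"T{i + 1}" for i in range(plan.n_tumor_samples)
    ]
    trait = np.array(
        [0] * plan.n_normal_samples + [1] * plan.n_tumor_samples
    )
    factors = rng.normal(size=(plan.n_modules, n_samples))
    factors[0, trait == 1] += plan.tumor_shift  # disease module is M1
    x = np.empty((plan.n_genes, n_samples))
    module_index = {f"M{m + 1}": m for m in range(plan.n_modules)}
    for i, g in enumerate(plan.gene_ids):
        lab = labels[g]
        if lab == GREY:
            x[i] = rng.normal(size=n_samples)
        else:
            x[i] = plan.loading * factors[module_index[lab]] + rng.normal(
                scale=plan.noise_sd, size=n_samples
            )
    matrix = pd.DataFrame(x, index=plan.gene_ids, columns=sample_ids)
    return ExpressionDataset(matrix=matrix, trait=trait), labels


def simulate_go(
    plan: SimulationPlan,
    module_labels: Mapping[str, str],
    cfg: PipelineConfig | None = None,
    n_random_terms: int = 6,
) -> tuple[dict[str, frozenset], dict[str, set]]:
    """GO-like structure: one term concentrated in the disease module, one
    strict-superset parent of it, and size-matched random terms.

    The enriched term takes 80% of its genes from the disease module; all
    terms have at least ``cfg.go_min_genes`` genes.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(plan.seed + 2)
    disease_genes = [
        g for g in plan.gene_ids
        if module_labels.get(g) == plan.disease_module
    ]
    other_genes = [
        g for g in plan.gene_ids
        if module_labels.get(g) != plan.disease_module
    ]
    if len(disease_genes) < cfg.go_min_genes:
        raise PlanError("disease module smaller than go_min_genes")
    term_size = max(2 * cfg.go_min_genes, 20)
    n_from_module = min(int(0.8 * term_size), len(disease_genes))
    n_from_other = term_size - n_from_module
    enriched = set(rng.choice(disease_genes, n_from_module, replace=False)) | set(
        rng.choice(other_genes, n_from_other, replace=False)
    )
    parent = enriched | set(
        rng.choice(
            [g for g in other_genes if g not in enriched], 10, replace=False
        )
    )
    term_to_genes = {
        "T_DISEASE": frozenset(enriched),
        "T_PARENT": frozenset(parent),
    }
    for i in range(n_random_terms):
        term_to_genes[f"T_RAND{i + 1}"] = frozenset(
            rng.choice(plan.gene_ids, term_size, replace=False)
        )
    parent_of = {"T_DISEASE": {"T_PARENT"}}
    return term_to_genes, parent_of


def expected_stage_sets(truth: pd.DataFrame) -> dict[str, set]:
    """Cascade stage membership implied by the truth table's fates.

    Returns stage -> set of (patient, chrom, pos, ref, alt) keys; the
    independent reference the realized cascade is compared against.
    """
    stages: dict[str, set] = {"QC": set(), "P": set(), "S": set(), "F": set()}
    for _, row in truth.iterrows():
        key = (
            row["patient_id"], row["chrom"], int(row["pos"]),
            row["ref"], row["alt"],
        )
        for stage in FATE_STAGES[row["fate"]]:
            stages[stage].add(key)
    return stages
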