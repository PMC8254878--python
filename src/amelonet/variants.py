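"""Somatic variant calling statistics and the four-stage filtration cascade.

The calling statistic is a Fisher exact test comparing alt-supporting read
counts between matched normal and tumor tissue at each candidate site.
Candidates then pass a quality-control (QC) gate, and QC survivors are
filtered in parallel by population rarity (P) and predicted severity (S);
the final set (F) is the intersection P ∩ S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

SEVERE_CONSEQUENCES = frozenset(
    {"frameshift", "stopgain", "stoploss", "startloss", "splice"}
)
CONSEQUENCES = SEVERE_CONSEQUENCES | {"missense", "synonymous", "other"}

#: The four East-Asian population-frequency databases consulted for rarity.
POPFREQ_DBS = ("1000g_eas", "exac_eas", "gnomad_genome_eas", "gnomad_exome_eas")


class DataError(ValueError):
    """Raised when an input value is outside its valid domain."""


@dataclass(frozen=True)
class VariantCandidate:
    """One putative somatic site with paired tumor/normal read counts.

    Positions are 1-based (VCF convention); records are keyed by
    (patient_id, chrom, pos, ref, alt).
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    normal_ref: int
    normal_alt: int
    tumor_ref: int
    tumor_alt: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("normal_ref", "normal_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} < 0 at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise DataError(f"pos must be 1-based positive, got {self.pos}")

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def normal_vaf(self) -> float:
        d = self.normal_depth
        return self.normal_alt / d if d > 0 else math.nan

    @property
    def tumor_vaf(self) -> float:
        d = self.tumor_depth
        return self.tumor_alt / d if d > 0 else math.nan


@dataclass(frozen=True)
class SomaticCall:
    """A candidate with its Fisher p-value, VAFs and QC verdict attached."""

    candidate: VariantCandidate
    fisher_p: float  # NaN when undefined (zero depth in a tissue)
    normal_vaf: float
    tumor_vaf: float
    qc_pass: bool


@dataclass(frozen=True)
class AnnotatedVariant:
    """A somatic call joined with gene/consequence/frequency annotation.

    ``popfreq`` maps each database name in :data:`POPFREQ_DBS` to a fraction,
    or ``None`` when the variant was never observed in that database.
    """

    call: SomaticCall
    gene: str
    consequence: str
    popfreq: Mapping[str, float | None]
    cadd_phred: float | None
    sift_damaging: bool | None
    polyphen_damaging: bool | None
    is_rare: bool
    is_severe: bool
    is_final: bool

    @property
    def candidate(self) -> VariantCandidate:
        return self.call.candidate


def fisher_p_values(
    normal_ref: np.ndarray,
    normal_alt: np.ndarray,
    tumor_ref: np.ndarray,
    tumor_alt: np.ndarray,
) -> np.ndarray:
    """Vectorized one-sided (tumor alt-enrichment) Fisher exact p-values.

    Conditional on the table margins, the tumor alt count follows a
    hypergeometric law; the one-sided p-value is its upper tail
    P(X >= tumor_alt).  Entries with zero depth in either tissue are NaN.
    """
    nr = np.asarray(normal_ref, dtype=np.int64)
    na = np.asarray(normal_alt, dtype=np.int64)
    tr = np.asarray(tumor_ref, dtype=np.int64)
    ta = np.asarray(tumor_alt, dtype=np.int64)
    total = nr + na + tr + ta
    alt_total = na + ta
    tumor_depth = tr + ta
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(ta - 1, total, alt_total, tumor_depth)
    p = np.minimum(np.asarray(p, dtype=float), 1.0)
    undefined = (nr + na == 0) | (tumor_depth == 0)
    return np.where(undefined, np.nan, p)


def fisher_somatic_test(
    c: VariantCandidate, alternative: str = "greater"
) -> float:
    """Fisher exact p-value for the 2x2 table [(normal_ref, normal_alt),
    (tumor_ref, tumor_alt)].

    The default is one-sided toward alt-read enrichment in tumor, the
    convention of somatic callers; ``alternative="two-sided"`` delegates to
    :func:`scipy.stats.fisher_exact`.

    Raises
    ------
    DataError
        If either tissue has zero total depth (the test is undefined).
    """
    if c.normal_depth == 0 or c.tumor_depth == 0:
        raise DataError(
            f"zero depth at {c.chrom}:{c.pos} — Fisher test undefined"
        )
    if alternative == "greater":
        return float(
            fisher_p_values(
                np.array([c.normal_ref]),
                np.array([c.normal_alt]),
                np.array([c.tumor_ref]),
                np.array([c.tumor_alt]),
            )[0]
        )
    if alternative == "two-sided":
        table = [[c.normal_ref, c.normal_alt], [c.tumor_ref, c.tumor_alt]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def apply_qc(call: SomaticCall, cfg: PipelineConfig) -> bool:
    """Quality-control gate on a somatic call.

    Passes iff ALL hold: Fisher p < qc_p_max; depth >= qc_depth_min in both
    tissues; normal alt reads <= qc_normal_alt_max; tumor alt reads >=
    qc_tumor_alt_min; normal VAF <= qc_normal_vaf_max; tumor VAF >=
    qc_tumor_vaf_min.  An undefined (NaN) p-value fails.
    """
    c = call.candidate
    if not (call.fisher_p < cfg.qc_p_max):  # NaN fails
        return False
    if c.normal_depth < cfg.qc_depth_min or c.tumor_depth < cfg.qc_depth_min:
        return False
    if c.normal_alt > cfg.qc_normal_alt_max:
        return False
    if c.tumor_alt < cfg.qc_tumor_alt_min:
        return False
    if not (call.normal_vaf <= cfg.qc_normal_vaf_max):
        return False
    if not (call.tumor_vaf >= cfg.qc_tumor_vaf_min):
        return False
    return True


def call_somatic(
    candidates: Iterable[VariantCandidate], cfg: PipelineConfig | None = None
) -> list[SomaticCall]:
    """Compute Fisher p, VAFs and the QC flag for each candidate.

    Zero-depth candidates get ``fisher_p = NaN`` and fail QC rather than
    raising, so a whole table can be processed in one pass.
    """
    cfg = cfg or PipelineConfig()
    calls = []
    for c in candidates:
        if c.normal_depth == 0 or c.tumor_depth == 0:
            p = math.nan
        else:
            p = fisher_somatic_test(c, cfg.fisher_alternative)
        call = SomaticCall(
            candidate=c,
            fisher_p=p,
            normal_vaf=c.normal_vaf,
            tumor_vaf=c.tumor_vaf,
            qc_pass=False,
        )
        calls.append(replace(call, qc_pass=apply_qc(call, cfg)))
    return calls


def flag_rare(v: AnnotatedVariant, cfg: PipelineConfig) -> bool:
    """True iff every non-missing population frequency is strictly below
    ``cfg.rare_freq_max``.

    A missing frequency means the allele was never observed in that
    database and is treated as 0 — the strongest possible rarity evidence.
    """
    for db in POPFREQ_DBS:
        f = v.popfreq.get(db)
        if f is None or (isinstance(f, float) and math.isnan(f)):
            continue
        if not 0.0 <= f <= 1.0:
            raise DataError(f"population frequency {f} outside [0,1] ({db})")
        if f >= cfg.rare_freq_max:
            return False
    return True


def flag_severe(v: AnnotatedVariant, cfg: PipelineConfig) -> bool:
    """Severity call.

    Frameshift/stopgain/stoploss/startloss/splice variants are severe by
    consequence class alone.  Missense (and 'other') variants are severe iff
    at least ``cfg.severe_tool_min`` of the three predictors flag them:
    CADD-phred >= cfg.cadd_min, SIFT damaging, PolyPhen-2 damaging.  A
    missing prediction counts as not damaging.
    """
    if v.consequence == "synonymous":
        raise DataError(
            "synonymous variant reached the severity filter; these must be "
            "discarded before filtration"
        )
    if v.consequence in SEVERE_CONSEQUENCES:
        return True
    n_damaging = 0
    if v.cadd_phred is not None and not (
        isinstance(v.cadd_phred, float) and math.isnan(v.cadd_phred)
    ):
        if v.cadd_phred >= cfg.cadd_min:
            n_damaging += 1
    if v.sift_damaging:
        n_damaging += 1
    if v.polyphen_damaging:
        n_damaging += 1
    return n_damaging >= cfg.severe_tool_min


def _clean_optional(x):
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def annotate_calls(
    calls: Iterable[SomaticCall],
    annotation: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> list[AnnotatedVariant]:
    """Join somatic calls with a site-level annotation table.

    ``annotation`` must carry columns chrom, pos, ref, alt, gene,
    consequence, the four frequencies in :data:`POPFREQ_DBS`, cadd_phred,
    sift_damaging, polyphen_damaging, keyed by (chrom, pos, ref, alt).
    Rarity/severity flags are computed here; synonymous variants keep
    ``is_severe = is_final = False`` (they are dropped by the cascade).
    """
    cfg = cfg or PipelineConfig()
    ann = annotation.set_index(["chrom", "pos", "ref", "alt"])
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise DataError(f"duplicate annotation for site {dup}")
    out = []
    for call in calls:
        c = call.candidate
        try:
            row = ann.loc[c.site]
        except KeyError:
            raise DataError(
                f"no annotation for site {c.chrom}:{c.pos} {c.ref}>{c.alt}"
            ) from None
        consequence = str(row["consequence"])
        if consequence not in CONSEQUENCES:
            raise DataError(f"unknown consequence {consequence!r}")
        v = AnnotatedVariant(
            call=call,
            gene=str(row["gene"]),
            consequence=consequence,
            popfreq={db: _clean_optional(row[db]) for db in POPFREQ_DBS},
            cadd_phred=_clean_optional(row["cadd_phred"]),
            sift_damaging=_clean_optional(row["sift_damaging"]),
            polyphen_damaging=_clean_optional(row["polyphen_damaging"]),
            is_rare=False,
            is_severe=False,
            is_final=False,
        )
        rare = flag_rare(v, cfg)
        severe = (
            False if consequence == "synonymous" else flag_severe(v, cfg)
        )
        out.append(
            replace(
                v,
                is_rare=rare,
                is_severe=severe,
                is_final=rare and severe and call.qc_pass
                and consequence != "synonymous",
            )
        )
    return out


@dataclass
class CascadeResult:
    """Output of the filtration cascade: the QC, rare (P), severe (S) and
    final (F = P ∩ S) variant sets, plus bookkeeping counts."""

    qc: list[AnnotatedVariant]
    rare: list[AnnotatedVariant]
    severe: list[AnnotatedVariant]
    final: list[AnnotatedVariant]
    n_input: int
    n_synonymous_discarded: int

    def stage_counts(self) -> pd.DataFrame:
        """Mutation and distinct-gene counts per cascade stage."""
        rows = []
        for stage, vs in (
            ("QC", self.qc),
            ("P", self.rare),
            ("S", self.severe),
            ("F", self.final),
        ):
            rows.append(
                {
                    "stage": stage,
                    "n_mutations": len(vs),
                    "n_genes": len({v.gene for v in vs}),
                }
            )
        return pd.DataFrame(rows)

    def per_patient_counts(self) -> pd.DataFrame:
        patients = sorted(
            {v.candidate.patient_id for v in self.qc}
            | {v.candidate.patient_id for v in self.final}
        )
        rows = []
        for p in patients:
            row = {"patient_id": p}
            for stage, vs in (
                ("QC", self.qc),
                ("P", self.rare),
                ("S", self.severe),
                ("F", self.final),
            ):
                row[stage] = sum(1 for v in vs if v.candidate.patient_id == p)
            rows.append(row)
        return pd.DataFrame(rows)


def run_cascade(
    variants: Sequence[AnnotatedVariant], cfg: PipelineConfig | None = None
) -> CascadeResult:
    """Run the filtration cascade QC → (P, S) → F.

    Synonymous variants are discarded up front.  QC is the quality gate;
    P keeps QC survivors that are rare in all four East-Asian databases;
    S keeps QC survivors with a severe consequence or >= 2 damaging
    predictions; F = P ∩ S.  Output order is canonical (sorted by variant
    key) so results are invariant to input permutation.
    """
    cfg = cfg or PipelineConfig()
    nonsyn = [v for v in variants if v.consequence != "synonymous"]
    n_syn = len(variants) - len(nonsyn)
    bykey = sorted(nonsyn, key=lambda v: v.candidate.key)
    qc = [v for v in bykey if v.call.qc_pass]
    rare = [v for v in qc if flag_rare(v, cfg)]
    severe = [v for v in qc if flag_severe(v, cfg)]
    rare_keys = {v.candidate.key for v in rare}
    final = [v for v in severe if v.candidate.key in rare_keys]
    return CascadeResult(
        qc=qc,
        rare=rare,
        severe=severe,
        final=final,
        n_input=len(variants),
        n_synonymous_discarded=n_syn,
    )


def recurrence_summary(finals: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Per-gene recurrence across patients of the final mutation set.

    Returns one row per gene with the set of patients carrying a final
    mutation in it, sorted by decreasing recurrence then gene symbol.
    """
    per_gene: dict[str, dict] = {}
    for v in finals:
        g = per_gene.setdefault(v.gene, {"patients": set(), "n_mutations": 0})
        g["patients"].add(v.candidate.patient_id)
        g["n_mutations"] += 1
    rows = [
        {
            "gene": gene,
            "n_patients": len(d["patients"]),
            "patients": ",".join(sorted(d["patients"])),
            "n_mutations": d["n_mutations"],
        }
        for gene, d in per_gene.items()
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "n_patients", "patients", "n_mutations"]
    )
    if len(df):
        df = df.sort_values(
            ["n_patients", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
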