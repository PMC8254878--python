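"""Readers and writers for every external representation the pipeline
touches: variant tables (TSV canonical, VCF read-only), expression
matrices with trait files, GMT term->gene files, parent-child term TSVs,
Cytoscape-style edge lists (SIF / weighted TSV) and the two-hit JSON.

No science lives here; coordinates are 1-based throughout and round-trips
are identities.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .coexpression import ExpressionDataset
from .integration import SubNetwork, TwoHitReport
from .variants import VariantCandidate

VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt",
    "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------- variants


def write_variant_table(
    candidates: Iterable[VariantCandidate], path: str | Path
) -> None:
    """Write candidates as the canonical 9-column TSV (with header)."""
    rows = [
        {col: getattr(c, col) for col in VARIANT_COLUMNS} for c in candidates
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _parse_tsv_variants(path: Path) -> list[VariantCandidate]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and fields[0] == "patient_id":
                continue
            if len(fields) != len(VARIANT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(VARIANT_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            try:
                out.append(
                    VariantCandidate(
                        patient_id=fields[0],
                        chrom=fields[1],
                        pos=int(fields[2]),
                        ref=fields[3],
                        alt=fields[4],
                        normal_ref=int(fields[5]),
                        normal_alt=int(fields[6]),
                        tumor_ref=int(fields[7]),
                        tumor_alt=int(fields[8]),
                    )
                )
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return out


def _parse_vcf_variants(
    path: Path, patient_id: str | None
) -> list[VariantCandidate]:
    """Read a paired VCF with NORMAL and TUMOR sample columns carrying AD.

    Multi-allelic records are split into one candidate per alt allele.
    """
    import pysam

    pid = patient_id or Path(path).stem
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if "NORMAL" not in samples or "TUMOR" not in samples:
            raise FormatError(
                f"{path}: VCF must carry NORMAL and TUMOR sample columns, "
                f"found {samples}"
            )
        out = []
        for rec in vf:
            nad = rec.samples["NORMAL"].get("AD")
            tad = rec.samples["TUMOR"].get("AD")
            if nad is None or tad is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD depths"
                )
            for i, alt in enumerate(rec.alts or (), start=1):
                out.append(
                    VariantCandidate(
                        patient_id=pid,
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam reports 1-based VCF POS
                        ref=rec.ref,
                        alt=alt,
                        normal_ref=int(nad[0]),
                        normal_alt=int(nad[i]),
                        tumor_ref=int(tad[0]),
                        tumor_alt=int(tad[i]),
                    )
                )
    return out


def read_variant_table(
    path: str | Path, dialect: str = "tsv", patient_id: str | None = None
) -> list[VariantCandidate]:
    """Read paired tumor/normal candidates from TSV (canonical) or VCF.

    The TSV dialect has the nine documented columns (header optional); the
    VCF dialect needs NORMAL and TUMOR sample columns with AD-style depths
    and takes the patient id from ``patient_id`` or the file stem.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if dialect == "tsv":
        return _parse_tsv_variants(p)
    if dialect == "vcf":
        return _parse_vcf_variants(p, patient_id)
    raise ValueError(f"unknown dialect {dialect!r}")


# -------------------------------------------------------------- expression


def write_expression_matrix(
    ds: ExpressionDataset, path: str | Path, trait_path: str | Path
) -> None:
    """Write the genes x samples matrix and the sample->tissue trait file."""
    out = ds.matrix.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "tissue": ["tumor" if t else "normal" for t in ds.trait],
        }
    ).to_csv(trait_path, sep="\t", index=False)


def read_expression_matrix(
    path: str | Path, trait_path: str | Path
) -> ExpressionDataset:
    """Read a genes x samples TSV plus its companion trait file.

    Rejects duplicated gene IDs and samples missing from the trait file.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].iloc[0]
        raise FormatError(f"{path}: duplicated gene ID {dup!r}")
    matrix = df.set_index(gene_col)
    matrix.index.name = None
    traits = pd.read_csv(trait_path, sep="\t")
    if not {"sample_id", "tissue"} <= set(traits.columns):
        raise FormatError(f"{trait_path}: need sample_id and tissue columns")
    tissue = dict(zip(traits["sample_id"].astype(str), traits["tissue"]))
    missing = [s for s in matrix.columns if s not in tissue]
    if missing:
        raise FormatError(
            f"{trait_path}: samples missing from trait file: {missing}"
        )
    bad = {t for t in tissue.values()} - {"normal", "tumor"}
    if bad:
        raise FormatError(f"{trait_path}: unknown tissue labels {sorted(bad)}")
    trait = np.array(
        [1 if tissue[s] == "tumor" else 0 for s in matrix.columns]
    )
    return ExpressionDataset(matrix=matrix, trait=trait)


# --------------------------------------------------------------- edge lists


def write_edge_list(
    net: SubNetwork, path: str | Path, fmt: str = "sif"
) -> None:
    """Export a sub-network for Cytoscape.

    SIF lines read ``geneA tom geneB``; the TSV variant adds the TOM weight
    with six decimals.  Each undirected edge is written once with the
    lexicographically smaller node first; isolated nodes appear as
    single-node SIF lines so they survive the export.
    """
    edges = net.edges  # already (min, max, weight), sorted
    connected = {u for u, v, _ in edges} | {v for u, v, _ in edges}
    isolated = [n for n in net.nodes if n not in connected]
    with open(path, "w") as fh:
        if fmt == "sif":
            for u, v, _ in edges:
                fh.write(f"{u}\ttom\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        elif fmt == "tsv":
            fh.write("gene_a\tgene_b\ttom\n")
            for u, v, w in edges:
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
        else:
            raise ValueError(f"unknown edge-list format {fmt!r}")


# ------------------------------------------------------------ GO structure


def write_gmt(term_to_genes: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_to_genes):
            genes = "\t".join(sorted(term_to_genes[term]))
            fh.write(f"{term}\t{term}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Read a GMT file: term, description, then one gene per column."""
    out: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT rows need term, description and "
                    "at least one gene"
                )
            if fields[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate term {fields[0]}")
            out[fields[0]] = frozenset(g for g in fields[2:] if g)
    return out


def write_parent_child(parent_of: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child in sorted(parent_of):
            for parent in sorted(parent_of[child]):
                fh.write(f"{child}\t{parent}\n")


def read_parent_child(path: str | Path) -> dict[str, set]:
    """Read the 2-column child->parent TSV (header 'child\\tparent')."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[:2] == ["child", "parent"]:
                continue
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


# ------------------------------------------------------------------ report


def write_two_hit_report(report: TwoHitReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_two_hit_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
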