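"""Three-layer evidence integration and prioritization.

Evidence is organized per miRNA implicated by the SNP layer (candidate-based:
downstream layers are only consulted for those miRNAs). A miRNA is *selected*
when all three layers support it under the trait-compatibility rule: the SNP
trait set is non-empty, at least one CpG trait falls inside the SNP trait
set, and at least one expression trait falls inside the SNP trait set — the
CpG-matched and expression-matched traits need not coincide with each other.
A selected miRNA is *prioritized* when its functional-evidence flag
(``eqtl_evidence``, supplied as input annotation: the SNP is a known
miR-eQTL for the miRNA) is true.

Layers that never tested a miRNA (no probe in the methylation data, mature
form not well-expressed, phenotype unavailable) are recorded as
``unavailable``, distinct from "tested, null".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

UNAVAILABLE = "unavailable"

PRIORITIZATION_FLAGS = ("eqtl_evidence", "tissue_expression", "structure_change")


@dataclass
class MirnaEvidence:
    """Per-miRNA evidence across the three omics layers."""

    mirna: str
    snp_traits: set[str]
    snp_best_p: float
    cpg_traits: set[str] | None  # None == layer unavailable
    expr_traits: set[str] | None
    eqtm_support: bool = False
    flags: dict[str, bool] = field(default_factory=dict)

    def layer_status(self, layer: str) -> str:
        traits = self.cpg_traits if layer == "cpg" else self.expr_traits
        if traits is None:
            return UNAVAILABLE
        return "supported" if traits else "null"


@dataclass
class EvidenceMatrix:
    """All per-miRNA evidence entries, keyed by miRNA id."""

    entries: dict[str, MirnaEvidence]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        return {
            "snp_layer": len(self.entries),
            "cpg_tested": sum(e.cpg_traits is not None for e in self),
            "cpg_supported": sum(bool(e.cpg_traits) for e in self),
            "expr_tested": sum(e.expr_traits is not None for e in self),
            "expr_supported": sum(bool(e.expr_traits) for e in self),
            "eqtm_support": sum(e.eqtm_support for e in self),
        }


@dataclass
class IntegrationRecord:
    """Final per-miRNA integration outcome."""

    mirna: str
    snp_traits: tuple[str, ...]
    cpg_shared_traits: tuple[str, ...]
    expr_shared_traits: tuple[str, ...]
    layers_supporting: tuple[str, ...]
    snp_best_p: float
    selected: bool
    prioritized: bool = False


def _sig_traits_per_mirna(results: pd.DataFrame, mirna_col: str) -> tuple[dict, dict]:
    """(tested miRNA -> set of significant traits, tested miRNA set helper)."""
    tested: dict[str, set[str]] = {}
    if results is None or results.empty:
        return tested, {}
    df = results
    if mirna_col == "mirna_ids":
        df = df.explode("mirna_ids").rename(columns={"mirna_ids": "mirna_id"})
        mirna_col = "mirna_id"
    best_p: dict[str, float] = {}
    for r in df.itertuples(index=False):
        mid = getattr(r, mirna_col)
        if pd.isna(mid):
            continue
        tested.setdefault(mid, set())
        if bool(getattr(r, "significant", False)):
            tested[mid].add(r.trait)
            p = float(getattr(r, "p", float("nan")))
            if mid not in best_p or p < best_p[mid]:
                best_p[mid] = p
    return tested, best_p


def build_evidence_matrix(
    snp_results: pd.DataFrame,
    cpg_results: pd.DataFrame | None = None,
    expr_results: pd.DataFrame | None = None,
    eqtm_crossref: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
    cpg_to_mirna: pd.DataFrame | None = None,
    mature_to_mirna: dict[str, str] | None = None,
    known_mirnas: set[str] | None = None,
) -> EvidenceMatrix:
    """Assemble one evidence entry per SNP-layer miRNA.

    ``snp_results``: SNP-layer AssociationResult rows (with ``mirna_ids``).
    ``cpg_results``: EWAS rows; CpGs map to miRNAs through ``cpg_to_mirna``
    (columns ``site_id``, ``mirna_id``). ``expr_results``: expression rows
    whose ``feature_id`` is a mature miRNA, mapped to the SNP-layer id
    scheme by ``mature_to_mirna`` (default identity). ``flags`` carries the
    prioritization booleans per miRNA. Downstream miRNA ids outside the
    annotation universe (``known_mirnas``, when given) raise.
    """
    snp_traits, snp_best_p = _sig_traits_per_mirna(snp_results, "mirna_ids")
    # the SNP layer *identifies* a miRNA only through significant evidence
    snp_traits = {m: t for m, t in snp_traits.items() if t}
    if not snp_traits:
        return EvidenceMatrix(entries={})

    universe = known_mirnas if known_mirnas is not None else None

    # CpG layer: probe-level results joined to miRNAs
    cpg_tested: dict[str, set[str]] = {}
    if cpg_results is not None and not cpg_results.empty:
        if cpg_to_mirna is None:
            raise ValueError("cpg_results given without cpg_to_mirna mapping")
        mapping = cpg_to_mirna.rename(columns={"site_id": "feature_id"})
        joined = cpg_results.merge(
            mapping[["feature_id", "mirna_id"]], on="feature_id", how="inner"
        )
        cpg_tested, _ = _sig_traits_per_mirna(joined, "mirna_id")

    # Expression layer: mature ids mapped onto the SNP-layer id scheme
    expr_tested: dict[str, set[str]] = {}
    if expr_results is not None and not expr_results.empty:
        mapper = mature_to_mirna or {}
        df = expr_results.copy()
        df["mirna_id"] = df["feature_id"].map(lambda m: mapper.get(m, m))
        expr_tested, _ = _sig_traits_per_mirna(df, "mirna_id")

    for layer_name, tested in (("cpg", cpg_tested), ("expression", expr_tested)):
        if universe is not None:
            unknown = sorted(set(tested) - universe)
            if unknown:
                raise ValueError(
                    f"{layer_name} layer names miRNAs absent from annotation: "
                    f"{unknown}"
                )

    eqtm_mirnas: set[str] = set()
    if eqtm_crossref is not None and not eqtm_crossref.empty:
        mapper = mature_to_mirna or {}
        eqtm_mirnas = {mapper.get(m, m) for m in eqtm_crossref["mirna"]}

    flag_map: dict[str, dict[str, bool]] = {}
    if flags is not None and not flags.empty:
        for r in flags.itertuples(index=False):
            flag_map[r.mirna] = {
                f: bool(getattr(r, f, False)) for f in PRIORITIZATION_FLAGS
            }

    entries = {}
    for mirna, traits in snp_traits.items():
        entries[mirna] = MirnaEvidence(
            mirna=mirna,
            snp_traits=traits,
            snp_best_p=snp_best_p.get(mirna, float("nan")),
            cpg_traits=cpg_tested.get(mirna),  # None when never tested
            expr_traits=expr_tested.get(mirna),
            eqtm_support=mirna in eqtm_mirnas,
            flags=flag_map.get(
                mirna, {f: False for f in PRIORITIZATION_FLAGS}
            ),
        )
    return EvidenceMatrix(entries=entries)


def select_multiomics(evidence: EvidenceMatrix) -> list[IntegrationRecord]:
    """Apply the trait-compatibility rule to every evidence entry.

    Selected iff the SNP trait set is non-empty and both the CpG and the
    expression layers each share at least one trait with it (an unavailable
    layer cannot support selection)."""
    records = []
    for e in evidence:
        cpg_shared = (e.cpg_traits or set()) & e.snp_traits
        expr_shared = (e.expr_traits or set()) & e.snp_traits
        layers = ["snp"] if e.snp_traits else []
        if cpg_shared:
            layers.append("cpg")
        if expr_shared:
            layers.append("expression")
        selected = bool(e.snp_traits) and bool(cpg_shared) and bool(expr_shared)
        records.append(
            IntegrationRecord(
                mirna=e.mirna,
                snp_traits=tuple(sorted(e.snp_traits)),
                cpg_shared_traits=tuple(sorted(cpg_shared)),
                expr_shared_traits=tuple(sorted(expr_shared)),
                layers_supporting=tuple(layers),
                snp_best_p=e.snp_best_p,
                selected=selected,
            )
        )
    return records


def prioritize(
    records: list[IntegrationRecord], evidence: EvidenceMatrix
) -> list[IntegrationRecord]:
    """Flag selected miRNAs with functional-eQTL evidence; sort by best
    SNP-layer p (ascending, miRNA id as deterministic tie-break)."""
    out = []
    for rec in records:
        flags = evidence.entries[rec.mirna].flags if rec.mirna in evidence.entries else {}
        rec.prioritized = rec.selected and flags.get("eqtl_evidence", False)
        out.append(rec)
    return sorted(out, key=lambda r: (not r.selected, r.snp_best_p, r.mirna))


def records_to_frame(records: list[IntegrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "snp_traits": ";".join(r.snp_traits),
                "cpg_shared_traits": ";".join(r.cpg_shared_traits),
                "expr_shared_traits": ";".join(r.expr_shared_traits),
                "layers_supporting": ";".join(r.layers_supporting),
                "snp_best_p": r.snp_best_p,
                "selected": r.selected,
                "prioritized": r.prioritized,
            }
            for r in records
        ],
        columns=["mirna", "snp_traits", "cpg_shared_traits",
                 "expr_shared_traits", "layers_supporting", "snp_best_p",
                 "selected", "prioritized"],
    )


def write_report(
    records: list[IntegrationRecord],
    evidence: EvidenceMatrix,
    outdir: str | Path,
    metadata: dict | None = None,
) -> dict:
    """Write ``integration_records.tsv`` + ``integration_report.json``.

    The JSON mirrors the per-stage counts (SNP-layer miRNAs, layers tested
    and supported, selected, prioritized) plus run metadata (seed, config
    hash). Returns the report dict. Deterministic: identical inputs yield
    byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    frame.to_csv(outdir / "integration_records.tsv", sep="\t", index=False)

    metadata = dict(metadata or {})
    config_hash = hashlib.sha256(
        json.dumps(metadata, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = {
        "counts": {
            **evidence.counts(),
            "selected": int(frame["selected"].sum()) if len(frame) else 0,
            "prioritized": int(frame["prioritized"].sum()) if len(frame) else 0,
        },
        "per_mirna": [
            {
                "mirna": e.mirna,
                "snp_traits": sorted(e.snp_traits),
                "cpg": e.layer_status("cpg"),
                "expression": e.layer_status("expression"),
                "eqtm_support": e.eqtm_support,
                "flags": e.flags,
            }
            for e in sorted(evidence, key=lambda e: e.mirna)
        ],
        "metadata": metadata,
        "config_hash": config_hash,
    }
    with open(outdir / "integration_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
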