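"""One round of the iterative motif-discovery loop, plus its reports.

The discovery loop alternates between this package and an external
structure predictor: scan candidate sequences for consensus windows,
analyse the predictor's ranked complex models into docking verdicts,
pick the headline verdict (the docked model with the most confident
motif region), and emit alanine-masked or truncated sequences whose next
prediction round can reveal secondary motifs.  The predictor itself is
an explicit external step — this module consumes its output files and
produces its next input, never runs it.

A candidate without model files is reported as ``awaiting prediction``,
not as a failure: that is the loop's normal intermediate state.  The
loop convention is to stop when a round produces no docked verdict.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import complex_interface as ci
from .conservation import AlignmentSet, conservation_score
from .pocket_atlas import PocketDefinition
from .seqmotif import (
    CANONICAL_PATTERN,
    MotifHit,
    ProteinRecord,
    get_pattern,
    mask_motif,
    read_fasta,
    scan,
    write_fasta,
)

__all__ = [
    "RoundConfig",
    "CandidateResult",
    "DiscoveryRound",
    "run_round",
    "emit_next_round",
    "pockets_hash",
    "validate_report",
]


@dataclass(frozen=True)
class RoundConfig:
    receptor_chain: str = "A"
    candidate_chain: str = "B"
    contact_cutoff_A: float = 4.5
    pattern: str = "canonical"
    flank_window: int = 4
    mask_strategy: str = "alanine"
    confident_above: float = 70.0


@dataclass
class CandidateResult:
    protein_id: str
    status: str  # "analysed" | "awaiting prediction"
    hits: list[MotifHit] = field(default_factory=list)
    verdicts: list[tuple[str, ci.DockingVerdict]] = field(default_factory=list)
    headline: ci.DockingVerdict | None = None
    headline_model: str | None = None
    disorder: str | None = None
    conserved_fraction: float | None = None


@dataclass
class DiscoveryRound:
    round_index: int
    results: list[CandidateResult]
    masked_loci: dict[str, list[tuple[int, int, str]]]
    pockets_sha: str
    next_fasta_path: Path | None = None


def pockets_hash(pockets: PocketDefinition) -> str:
    payload = json.dumps(
        {"w": sorted(pockets.w_site), "l": sorted(pockets.l_site)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _find_models(models_dir: Path, protein_id: str) -> list[Path]:
    paths = []
    for suffix in ("*.pdb", "*.cif", "*.mmcif"):
        paths.extend(models_dir.glob(f"{protein_id}*{suffix[1:]}"))
    return sorted(set(paths))


def _find_scores(structure_path: Path) -> Path | None:
    sib = structure_path.with_suffix(".json")
    if sib.exists():
        return sib
    alt = structure_path.with_name(
        structure_path.stem.replace("unrelaxed", "scores") + ".json"
    )
    if alt.exists():
        return alt
    return None


def run_round(
    candidates: Sequence[ProteinRecord] | str | Path,
    models_dir: str | Path,
    pockets: PocketDefinition,
    config: RoundConfig = RoundConfig(),
    round_index: int = 1,
    prior_masked: Mapping[str, Sequence[tuple[int, int, str]]] | None = None,
    monomer_plddt: Mapping[str, Sequence[float]] | None = None,
    msas: Mapping[str, AlignmentSet] | None = None,
    out_dir: str | Path | None = None,
) -> DiscoveryRound:
    """Scan, analyse and report one discovery round.

    Per candidate: consensus scan of the sequence, per-model docking
    verdicts against ``pockets``, headline verdict from interface-
    confidence model ranking, plus disorder context (when single-chain
    pLDDT is supplied) and anchor conservation (when an MSA is
    supplied).  Writes ``report.json`` and ``report.tsv`` to ``out_dir``
    when given.
    """
    if isinstance(candidates, (str, Path)):
        candidates = read_fasta(candidates)
    models_dir = Path(models_dir)
    pattern = get_pattern(config.pattern)
    masked: dict[str, list[tuple[int, int, str]]] = {
        k: list(v) for k, v in (prior_masked or {}).items()
    }

    results: list[CandidateResult] = []
    for record in candidates:
        res = CandidateResult(protein_id=record.id, status="analysed")
        res.hits = scan(record, pattern, flank_window=config.flank_window)
        model_paths = _find_models(models_dir, record.id)
        if not model_paths:
            res.status = "awaiting prediction"
            results.append(res)
            continue
        models = [
            ci.load_model(p, _find_scores(p)) for p in model_paths
        ]
        ranked = ci.rank_models(
            models,
            pockets,
            config.receptor_chain,
            config.candidate_chain,
            config.contact_cutoff_A,
        )
        res.verdicts = [(m.model_id, v) for m, v in ranked]
        head_model, head_verdict = ranked[0]
        res.headline = head_verdict
        res.headline_model = head_model.model_id
        if monomer_plddt and record.id in monomer_plddt and res.hits:
            first = res.hits[0]
            res.disorder = ci.disorder_context(
                monomer_plddt[record.id], first
            )
        if msas and record.id in msas and head_verdict.docked:
            hit = _verdict_to_hit(record, head_verdict, pattern.name)
            if hit is not None:
                res.conserved_fraction = conservation_score(
                    msas[record.id], hit, pattern
                ).fraction_retained
        results.append(res)

    rnd = DiscoveryRound(
        round_index=round_index,
        results=results,
        masked_loci=masked,
        pockets_sha=pockets_hash(pockets),
    )
    if out_dir is not None:
        write_report(rnd, Path(out_dir), models_dir)
    return rnd


def _verdict_to_hit(
    record: ProteinRecord, verdict: ci.DockingVerdict, pattern_name: str
) -> MotifHit | None:
    """Translate a docked verdict into sequence coordinates.

    Assumes the candidate chain numbering matches the 1-based sequence
    positions of the record (true for predictor output on the full
    sequence); returns None when the core does not line up, e.g. after
    truncation shifted the register.
    """
    assert verdict.w_occupant is not None and verdict.l_occupant is not None
    start, end = verdict.w_occupant.position, verdict.l_occupant.position
    if not (1 <= start <= end <= len(record)):
        return None
    core = record.subsequence(start, end)
    if verdict.core_sequence is not None and core != verdict.core_sequence:
        return None
    return MotifHit(
        protein_id=record.id,
        start=start,
        end=end,
        core=core,
        pattern_name=pattern_name,
    )


def emit_next_round(
    record: ProteinRecord,
    verdict: ci.DockingVerdict,
    strategy: str = "alanine",
    out_path: str | Path | None = None,
    round_index: int = 1,
) -> tuple[ProteinRecord, tuple[int, int, str]]:
    """Mask the verdict's core locus and emit the next-round sequence.

    Returns the masked record (id suffixed with the next round) and the
    ``(start, end, strategy)`` locus tuple to accumulate in the round
    manifest.  Raises when the verdict is not docked — there is nothing
    to mask.
    """
    if not verdict.docked:
        raise ValueError("verdict is not docked: nothing to mask")
    hit = _verdict_to_hit(record, verdict, "docked")
    if hit is None:
        raise ValueError(
            "docked core does not line up with the candidate sequence; "
            "was the record already truncated?"
        )
    masked = mask_motif(record, hit, strategy=strategy)
    masked = ProteinRecord(
        f"{record.id}_round{round_index + 1}", masked.sequence, record.organism
    )
    if out_path is not None:
        write_fasta([masked], out_path)
    return masked, (hit.start, hit.end, strategy)


# --- reporting -------------------------------------------------------------

_TSV_COLUMNS = [
    "protein_id", "round", "status", "w_pos", "l_pos", "core", "class",
    "separation", "interface_plddt", "bin", "conserved_fraction", "disorder",
]


def _result_row(res: CandidateResult, round_index: int) -> dict:
    v = res.headline
    return {
        "protein_id": res.protein_id,
        "round": round_index,
        "status": res.status,
        "w_pos": v.w_occupant.position if v and v.w_occupant else None,
        "l_pos": v.l_occupant.position if v and v.l_occupant else None,
        "core": v.core_sequence if v else None,
        "class": v.motif_class if v else "none",
        "separation": v.separation if v else None,
        "interface_plddt": v.interface_plddt if v else None,
        "bin": v.confidence_bin if v else "none",
        "conserved_fraction": res.conserved_fraction,
        "disorder": res.disorder,
    }


def round_report(rnd: DiscoveryRound, models_dir: Path | None = None) -> dict:
    report = {
        "round_index": rnd.round_index,
        "pockets_sha": rnd.pockets_sha,
        "models_dir": str(models_dir) if models_dir else None,
        "masked_loci": {
            k: [list(t) for t in v] for k, v in rnd.masked_loci.items()
        },
        "candidates": [],
    }
    for res in rnd.results:
        entry = _result_row(res, rnd.round_index)
        entry["n_scan_hits"] = len(res.hits)
        entry["models"] = [
            {
                "model_id": mid,
                "docked": v.docked,
                "motif_class": v.motif_class,
                "core": v.core_sequence,
                "interface_plddt": v.interface_plddt,
                "confidence_bin": v.confidence_bin,
                "reason": v.reason,
            }
            for mid, v in res.verdicts
        ]
        report["candidates"].append(entry)
    return report


def write_report(
    rnd: DiscoveryRound, out_dir: Path, models_dir: Path | None = None
) -> tuple[Path, Path]:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    report = round_report(rnd, models_dir)
    validate_report(report)
    json_path = out_dir / f"round{rnd.round_index}_report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    rows = [_result_row(res, rnd.round_index) for res in rnd.results]
    tsv_path = out_dir / f"round{rnd.round_index}_report.tsv"
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False
    )
    return json_path, tsv_path


def _check(instance, schema, path="$") -> list[str]:
    """Minimal structural validator for the shipped report schema subset."""
    errors = []
    t = schema.get("type")
    types = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if instance is None:
        if not schema.get("nullable", False):
            errors.append(f"{path}: null not allowed")
        return errors
    if t:
        bad_bool = t == "number" and isinstance(instance, bool)
        if bad_bool or not isinstance(instance, types[t]):
            errors.append(
                f"{path}: expected {t}, got {type(instance).__name__}"
            )
            return errors
    if t == "object" and isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    if t == "array" and isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            errors.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> None:
    """Check a round report against the shipped schema; raise on failure."""
    from importlib import resources

    schema = json.loads(
        (resources.files("aimdock.data") / "report_schema.json").read_text()
    )
    errors = _check(report, schema)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))
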