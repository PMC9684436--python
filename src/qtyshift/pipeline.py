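"""End-to-end orchestration: fetch -> convert -> properties -> superpose.

``run_report`` walks a list of targets, produces for each a native/QTY
row pair in a sequence report (pI, MW in kDa, TM and overall variation %)
and, when coordinate files are supplied, a structural report with raw and
refined RMSD. One broken target never aborts the run: its error is
recorded and the report stays partial.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .qty import ProteinRecord, attach_tm, qty_convert, read_fasta, read_tm_intervals, round2
from .seqprops import sequence_properties
from .structure import map_sequence_to_structure, read_structure
from .superpose import superpose_models, trim_outside_tm
from .uniprot import fetch_uniprot


@dataclass(frozen=True)
class Target:
    name: str
    accession: str = ""
    fasta: str = ""  # alternative to accession: local FASTA path
    pdb: str = ""  # experimental structure path (optional)
    model_native: str = ""  # predicted native model path (optional)
    model_qty: str = ""  # predicted QTY-variant model path (optional)
    chain: str = ""


@dataclass(frozen=True)
class RunConfig:
    targets: tuple[Target, ...]
    out_dir: str
    tm_source: str = "uniprot"  # or "file"
    tm_file: str = ""
    cache_dir: str = ""
    seed: int = 0
    offline: bool = False
    trim_to_tm: bool = True
    cycles: int = 5
    reject_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("config must name at least one target")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        targets = tuple(Target(**t) for t in raw.pop("targets"))
        return cls(targets=targets, **raw)


def _load_record(target: Target, config: RunConfig) -> ProteinRecord:
    if target.fasta:
        rec = read_fasta(target.fasta)[0]
        rec = ProteinRecord(id=target.name, sequence=rec.sequence,
                            description=rec.description, tm_segments=rec.tm_segments)
    elif target.accession:
        cache = config.cache_dir or str(Path(config.out_dir) / "cache")
        rec = fetch_uniprot(target.accession, cache, offline=config.offline)
        rec = ProteinRecord(id=target.name, sequence=rec.sequence,
                            description=rec.description, tm_segments=rec.tm_segments)
    else:
        raise ValueError(f"target {target.name}: neither accession nor fasta given")
    if config.tm_source == "file":
        table = read_tm_intervals(config.tm_file)
        key = target.name if target.name in table else target.accession
        rec = attach_tm(rec, table.get(key, []))
    return rec


def _structure_rmsd(record: ProteinRecord, ref_path: str, mob_path: str,
                    chain: str, config: RunConfig):
    ref = read_structure(ref_path, chain=chain or None)
    mob = read_structure(mob_path, chain=None)
    pair_map = map_sequence_to_structure(record, ref)
    trim = trim_outside_tm(record, pair_map) if config.trim_to_tm else None
    return superpose_models(ref, mob, pair_map=pair_map, trim=trim,
                            cycles=config.cycles, reject_cutoff=config.reject_cutoff)


def run_report(config: RunConfig) -> dict:
    """Run all targets; write sequence_report.tsv, structure_report.tsv, run_log.json.

    Returns a summary dict with the output paths, per-target errors, and
    ``exit_code`` (0 = full success, 2 = partial failure).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq_rows: list[dict] = []
    struct_rows: list[dict] = []
    errors: dict[str, str] = {}

    for target in config.targets:
        try:
            record = _load_record(target, config)
            result = qty_convert(record)
            p_nat = sequence_properties(record.sequence)
            p_qty = sequence_properties(result.variant_sequence)
            seq_rows.append({
                "name": target.name, "rmsd_A": "",
                "pI": f"{round2(p_nat.pi):.2f}", "MW_kDa": f"{round2(p_nat.mw_kda):.2f}",
                "TM_variation_pct": "", "overall_variation_pct": "",
            })
            rmsd_qty = ""
            if target.pdb and target.model_qty:
                res = _structure_rmsd(
                    attach_tm(ProteinRecord(id=record.id, sequence=result.variant_sequence,
                                            description=""), record.tm_segments),
                    target.pdb, target.model_qty, target.chain, config)
                rmsd_qty = f"{res.rmsd_refined:.3f}"
                row = {"name": target.name, "pdb": Path(target.pdb).stem,
                       "rmsd_qty_pdb_A": rmsd_qty, "rmsd_native_pdb_A": "",
                       "n_pairs": res.n_pairs_retained}
                if target.model_native:
                    res_n = _structure_rmsd(record, target.pdb, target.model_native,
                                            target.chain, config)
                    row["rmsd_native_pdb_A"] = f"{res_n.rmsd_refined:.3f}"
                struct_rows.append(row)
            seq_rows.append({
                "name": target.name + "_QTY",
                "rmsd_A": rmsd_qty,
                "pI": f"{round2(p_qty.pi):.2f}", "MW_kDa": f"{round2(p_qty.mw_kda):.2f}",
                "TM_variation_pct": f"{round2(result.stats.tm_variation_pct):.2f}",
                "overall_variation_pct": f"{round2(result.stats.overall_variation_pct):.2f}",
            })
        except Exception as exc:  # per-target isolation
            errors[target.name] = f"{type(exc).__name__}: {exc}"

    seq_path = out / "sequence_report.tsv"
    pd.DataFrame(seq_rows).to_csv(seq_path, sep="\t", index=False)
    struct_path = out / "structure_report.tsv"
    pd.DataFrame(struct_rows).to_csv(struct_path, sep="\t", index=False)
    log = {
        "qtyshift_version": __version__,
        "seed": config.seed,
        "date": _dt.date.today().isoformat(),
        "n_targets": len(config.targets),
        "n_failed": len(errors),
        "errors": errors,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "sequence_report": str(seq_path),
        "structure_report": str(struct_path),
        "errors": errors,
        "exit_code": 2 if errors else 0,
    }
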