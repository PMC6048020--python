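"""File-format readers and writers shared by all stages.

Plain-text formats only: FASTA for proteomes (via Biopython), TSV for
plates, quantification tables, rate tables and matrices (tab separation,
'.' decimals, '\\n' line endings, header row), JSON for fit results,
truth records and reports.  Writers are byte-stable for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profile import AA20, SpecificityMatrix
from .pics import CleavageEvent, ProteinRecord
from .psscl import PSSCLPlate

log = logging.getLogger(__name__)


def read_fasta(path: str | Path, invalid: str = "reject") -> list[ProteinRecord]:
    """Load a proteome; ids are the header token up to the first whitespace.

    ``invalid`` controls records with symbols outside the 20-letter
    alphabet: ``"reject"`` raises, ``"drop"`` excludes the record and
    logs it.
    """
    if invalid not in ("reject", "drop"):
        raise ValueError("invalid policy must be 'reject' or 'drop'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - set(AA20)
        if bad:
            if invalid == "reject":
                raise ValueError(f"record {rec.id!r} contains invalid symbols {sorted(bad)}")
            n_dropped += 1
            continue
        records.append(ProteinRecord(rec.id, seq))
    if n_dropped:
        log.info("dropped %d record(s) with non-canonical symbols", n_dropped)
    if not records:
        raise ValueError(f"no usable records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_matrix(m: SpecificityMatrix, path: str | Path) -> None:
    """Matrix TSV (first column: amino acid) + JSON sidecar with metadata."""
    path = Path(path)
    df = m.values.copy()
    df.index.name = "aa"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
    sidecar = {
        "mode": m.mode,
        "n_events": None if m.n_events is None else {k: int(v) for k, v in m.n_events.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_matrix(path: str | Path) -> SpecificityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    mode, n_events = "counts", None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        mode = sidecar.get("mode", "counts")
        if sidecar.get("n_events") is not None:
            n_events = pd.Series(sidecar["n_events"]).reindex(df.columns)
    return SpecificityMatrix(df, mode=mode, n_events=n_events)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Peptide quantification TSV: peptide, intensity_treated, intensity_control."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "intensity_treated", "intensity_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quantification table missing columns: {sorted(missing)}")
    return df


def write_quant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_plate(path: str | Path) -> PSSCLPlate:
    """PSSCL plate TSV: sublibrary, fixed_residue, replicate, rate[, blank]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sublibrary", "fixed_residue", "replicate", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if "blank" not in df.columns:
        df["blank"] = 0.0
    return PSSCLPlate.from_frame(df)


def write_plate(plate: PSSCLPlate, path: str | Path) -> None:
    plate.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_events(events: list[CleavageEvent], path: str | Path) -> None:
    rows = [
        (e.protein_id, e.p1_index, e.window.residues, f"{e.fold_change:.6g}", e.neo_terminus)
        for e in events
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "p1_index", "window", "fold_change", "neo_terminus"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Rate TSV: substrate_uM, modifier_uM, replicate, rate columns."""
    df = pd.read_csv(path, sep="\t")
    if "rate" not in df.columns:
        raise ValueError("rate table must have a 'rate' column")
    return df


def read_progress_curve(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"time", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"progress curve missing columns: {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
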