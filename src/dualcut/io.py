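"""Reading and writing the standard formats the pipeline exchanges.

FASTA/FASTQ through Biopython; droplet panels as plain CSV with the dialect
(droplet_id, volume_nl, ch1, ch2, valid); loci, truth and sample metadata as
JSON; simulation configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cdpcr import REQUIRED_DROPLET_COLUMNS
from .editsim import SimRead
from .locus import GuideSite, LocusPair


def write_fastq(reads, path) -> None:
    records = [
        SeqRecord(
            Seq(r.seq),
            id=r.read_id,
            description=f"label={r.label}",
            letter_annotations={"phred_quality": [40] * len(r.seq)},
        )
        for r in reads
    ]
    SeqIO.write(records, str(path), "fastq")


def write_fasta(reads, path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.read_id, description=f"label={r.label}") for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[SimRead]:
    """Load FASTA/FASTQ reads; truth labels are recovered when present."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        label = "unknown"
        for tok in rec.description.split():
            if tok.startswith("label="):
                label = tok[len("label="):]
        out.append(SimRead(read_id=rec.id, seq=str(rec.seq).upper(), label=label))
    return out


def write_droplet_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_droplet_csv(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = [c for c in REQUIRED_DROPLET_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"droplet CSV missing required columns: {missing}")
    return panel


def locus_to_dict(locus: LocusPair) -> dict:
    return {
        "chrom_name": locus.chrom_name,
        "ref_segment": locus.ref_segment,
        "fixed_cut_pos": locus.fixed_cut_pos,
        "variable_cut_pos": locus.variable_cut_pos,
        "fixed_guide": vars(locus.fixed_guide).copy(),
        "variable_guide": vars(locus.variable_guide).copy(),
    }


def locus_from_dict(d: dict) -> LocusPair:
    return LocusPair(
        chrom_name=d["chrom_name"],
        ref_segment=d["ref_segment"],
        fixed_cut_pos=int(d["fixed_cut_pos"]),
        variable_cut_pos=int(d["variable_cut_pos"]),
        fixed_guide=GuideSite(**d["fixed_guide"]),
        variable_guide=GuideSite(**d["variable_guide"]),
    )


def write_locus(locus: LocusPair, path) -> None:
    Path(path).write_text(json.dumps(locus_to_dict(locus), indent=2))


def read_locus(path) -> LocusPair:
    return locus_from_dict(json.loads(Path(path).read_text()))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
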