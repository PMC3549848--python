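"""File formats, the benchmark-instance registry, and run manifests.

Formats
-------
plain-HP text    one record per line, ``name<TAB>HPstring`` or a bare HP
                 string; ``#`` starts a comment line.
FASTA            standard multi-record amino-acid FASTA, converted to HP
                 via the 10/10 hydrophobicity partition.
conformation TSV columns ``index residue x y z``, 0-based index.
run log TSV      columns ``iteration current_energy best_energy event``.
config file      flat ``key: value`` mapping (YAML subset) with RunConfig
                 field names as keys.
manifest JSON    seed, config, sequence and version — enough to reproduce
                 a run bit-identically.
schematic PDB    one CA pseudo-atom per residue at lattice coordinates
                 scaled by 3.8/sqrt(2) A so bonded residues sit ~3.8 A
                 apart; a viewer convenience, not a physical model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from Bio import SeqIO

from . import __version__
from .analysis import load_benchmark_table
from .conformation import (
    Conformation,
    HPSequence,
    aa_to_hp,
    as_hp_sequence,
)
from .search import LogRow, RunConfig

__all__ = [
    "read_hp_file",
    "write_hp_file",
    "read_fasta_hp",
    "write_conformation_tsv",
    "read_conformation_tsv",
    "write_run_log",
    "read_config_file",
    "write_manifest",
    "write_schematic_pdb",
    "InstanceRecord",
    "load_instances",
]

#: Lattice-unit -> Angstrom scale putting bonded residues ~3.8 A apart.
PDB_SCALE = 3.8 / math.sqrt(2.0)


def read_hp_file(path) -> List[Tuple[str, HPSequence]]:
    """Parse a plain-HP text file into (name, sequence) records.

    Unnamed records get names ``seq1, seq2, ...`` in file order.
    """
    records = []
    counter = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        counter += 1
        if "\t" in line:
            name, seq = line.split("\t", 1)
        else:
            name, seq = f"seq{counter}", line
        records.append((name.strip(), HPSequence(seq.strip())))
    return records


def write_hp_file(path, records) -> None:
    lines = [f"{name}\t{as_hp_sequence(seq).residues}" for name, seq in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_hp(path) -> List[Tuple[str, HPSequence]]:
    """Read amino-acid FASTA records and reduce each to HP."""
    return [
        (record.id, aa_to_hp(str(record.seq)))
        for record in SeqIO.parse(str(path), "fasta")
    ]


def write_conformation_tsv(conf: Conformation, path) -> None:
    lines = ["index\tresidue\tx\ty\tz"]
    for i, (x, y, z) in enumerate(conf.coords):
        lines.append(f"{i}\t{conf.sequence.residues[i]}\t{x}\t{y}\t{z}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_conformation_tsv(path, validate: bool = True) -> Conformation:
    """Read a conformation TSV; with ``validate`` the chain invariants are
    enforced (raising ConformationError naming the violation)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["index", "residue", "x", "y", "z"]:
        raise ValueError(f"{path}: not a conformation TSV (bad header)")
    residues, coords = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields")
        idx, res, x, y, z = fields
        if int(idx) != len(residues):
            raise ValueError(f"{path}:{lineno}: indices out of order")
        residues.append(res)
        coords.append((int(x), int(y), int(z)))
    return Conformation(HPSequence("".join(residues)), coords, validate=validate)


def write_run_log(log: List[LogRow], path) -> None:
    lines = ["iteration\tcurrent_energy\tbest_energy\tevent"]
    lines += [f"{it}\t{e}\t{b}\t{ev}" for it, e, b, ev in log]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config_file(path) -> RunConfig:
    """Flat key:value config; keys are RunConfig field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("energy_window", "structure_window"):
        if key in data:
            data[key] = tuple(data[key])
    config = RunConfig(**data)
    config.validate()
    return config


def write_manifest(
    path,
    sequence,
    config: RunConfig,
    runs: int = 1,
    extra: Optional[Dict] = None,
) -> None:
    manifest = {
        "package": "spiralfold",
        "version": __version__,
        "sequence": as_hp_sequence(sequence).residues,
        "runs": runs,
        "config": dataclasses.asdict(config),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def write_schematic_pdb(conf: Conformation, path) -> None:
    """Schematic CA-trace PDB export (one pseudo-atom per residue)."""
    lines = [
        "REMARK   1 SCHEMATIC LATTICE MODEL: ONE CA PSEUDO-ATOM PER RESIDUE",
        "REMARK   1 FCC LATTICE COORDINATES SCALED BY 3.8/SQRT(2) ANGSTROM",
    ]
    for i, (x, y, z) in enumerate(conf.coords):
        res = "PHE" if conf.sequence.residues[i] == "H" else "SER"
        lines.append(
            f"ATOM  {i + 1:>5}  CA  {res} A{i + 1:>4}    "
            f"{x * PDB_SCALE:8.3f}{y * PDB_SCALE:8.3f}{z * PDB_SCALE:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass(frozen=True)
class InstanceRecord:
    """Registry metadata for one benchmark instance.

    ``sequence`` is populated only when the user supplies the external
    sequence files; the benchmark set itself is not redistributed.
    """

    id: str
    group: str
    size: int
    lb_free_energy: Optional[int]
    sequence: Optional[HPSequence] = None

    @property
    def external(self) -> bool:
        return self.sequence is None


def load_instances(sequence_dir=None) -> List[InstanceRecord]:
    """The 21-instance benchmark registry.

    With ``sequence_dir``, files named ``<id>.hp`` (plain-HP format) are
    attached to their records; a supplied sequence whose length conflicts
    with the registry size is an error naming the instance.
    """
    table = load_benchmark_table()
    records = []
    for _, row in table.iterrows():
        seq = None
        if sequence_dir is not None:
            candidate = Path(sequence_dir) / f"{row['id']}.hp"
            if candidate.exists():
                seq = read_hp_file(candidate)[0][1]
                if len(seq) != int(row["size"]):
                    raise ValueError(
                        f"instance {row['id']}: supplied sequence has "
                        f"{len(seq)} residues, registry says {int(row['size'])}"
                    )
        lb = row["lb_free_energy"]
        records.append(
            InstanceRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                size=int(row["size"]),
                lb_free_energy=int(lb) if not math.isnan(lb) else None,
                sequence=seq,
            )
        )
    return records
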