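"""TSV/FASTA/JSON readers and writers for the package's data formats.

All tabular formats are UTF-8 TSV with a header row and ``#`` comments;
column order is deterministic.
"""

from __future__ import annotations

import json
from os import PathLike

import pandas as pd
from Bio import SeqIO

from .decoding import ConcentrationProfile, normalize_codon
from .elongation import DwellDecomposition
from .rates import RATE_NAMES, RateSet

__all__ = [
    "read_rate_set",
    "write_rate_set",
    "read_concentrations",
    "write_concentrations",
    "read_usage",
    "write_usage",
    "write_shifts",
    "read_shifts",
    "read_coding_sequence",
    "usage_from_fasta",
    "dwell_to_json",
]

_RATE_UNITS = {name: "1/s" for name in RATE_NAMES}
_RATE_UNITS["kon"] = "1/(uM*s)"


def read_rate_set(path: str | PathLike, label: str = "") -> tuple[RateSet, dict[str, float]]:
    """Read a rate TSV (rate_name, value, units, temperature_K, rel_error).

    Returns the rate set and the relative errors (zero where blank).
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"rate_name", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: rate TSV needs columns {sorted(required)}")
    values: dict[str, float] = {}
    rel_errors: dict[str, float] = {}
    temperature = 310.0
    for _, row in table.iterrows():
        name = str(row["rate_name"])
        if name not in RATE_NAMES:
            raise ValueError(f"{path}: unknown rate name {name!r}")
        values[name] = float(row["value"])
        if "rel_error" in table.columns and pd.notna(row.get("rel_error")):
            rel_errors[name] = float(row["rel_error"])
        if "temperature_K" in table.columns and pd.notna(row.get("temperature_K")):
            temperature = float(row["temperature_K"])
    missing = set(RATE_NAMES) - set(values)
    if missing:
        raise ValueError(f"{path}: missing rates {sorted(missing)}")
    return RateSet(temperature=temperature, label=label or str(path), **values), rel_errors


def write_rate_set(rates: RateSet, path: str | PathLike,
                   rel_errors: dict[str, float] | None = None) -> None:
    rel_errors = rel_errors or {}
    rows = [
        {
            "rate_name": name,
            "value": rates[name],
            "units": _RATE_UNITS[name],
            "temperature_K": rates.temperature,
            "rel_error": rel_errors.get(name, 0.0),
        }
        for name in RATE_NAMES
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_concentrations(path: str | PathLike, growth_label: str = "") -> ConcentrationProfile:
    """Read a concentration TSV (trna_id, concentration_uM)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"trna_id", "concentration_uM"}.issubset(table.columns):
        raise ValueError(f"{path}: concentration TSV needs columns trna_id, concentration_uM")
    conc = {str(r["trna_id"]): float(r["concentration_uM"]) for _, r in table.iterrows()}
    return ConcentrationProfile(concentrations=conc, growth_label=growth_label)


def write_concentrations(profile: ConcentrationProfile, path: str | PathLike) -> None:
    rows = [
        {"trna_id": trna, "concentration_uM": c}
        for trna, c in profile.concentrations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_usage(path: str | PathLike) -> dict[str, float]:
    """Read a codon-usage TSV (codon, probability)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"codon": str})
    if not {"codon", "probability"}.issubset(table.columns):
        raise ValueError(f"{path}: usage TSV needs columns codon, probability")
    return {
        normalize_codon(r["codon"]): float(r["probability"]) for _, r in table.iterrows()
    }


def write_usage(usage: dict[str, float], path: str | PathLike) -> None:
    rows = [{"codon": c, "probability": p} for c, p in usage.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_shifts(deltas: dict[str, float], path: str | PathLike) -> None:
    rows = [{"rate_name": n, "delta": d} for n, d in deltas.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_shifts(path: str | PathLike) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t", comment="#")
    return {str(r["rate_name"]): float(r["delta"]) for _, r in table.iterrows()}


def read_coding_sequence(path: str | PathLike) -> tuple[str, ...]:
    """Read the first record of a FASTA file as a codon tuple (RNA alphabet)."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"{path}: no FASTA records")
    seq = str(record.seq).upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise ValueError(f"{path}: sequence length {len(seq)} is not a multiple of 3")
    return tuple(seq[i:i + 3] for i in range(0, len(seq), 3))


def usage_from_fasta(path: str | PathLike) -> dict[str, float]:
    """Codon usage estimated by counting codons over all coding sequences in a FASTA file."""
    counts: dict[str, int] = {}
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq).upper().replace("T", "U")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if len(codon) == 3 and all(b in "ACGU" for b in codon):
                try:
                    codon = normalize_codon(codon)
                except ValueError:
                    continue  # stop codons do not contribute to elongation
                counts[codon] = counts.get(codon, 0) + 1
    if n_records == 0 or not counts:
        raise ValueError(f"{path}: no codons found")
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def dwell_to_json(dwell: DwellDecomposition, path: str | PathLike | None = None) -> str:
    """Deterministic JSON export of a dwell decomposition (17 significant digits)."""
    payload = json.dumps(
        {k: float(repr(v)) for k, v in dwell.as_dict().items()},
        indent=2, sort_keys=True,
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload + "\n")
    return payload
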