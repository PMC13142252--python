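"""Machine-readable catalogue of the 13 studied FSHR missense variants.

Each record carries the mutation label (wild-type residue, 1-based
position, substituting residue), the receptor domain harbouring it
(ectodomain, one of the seven transmembrane helices, or an
extracellular loop), the pharmacoperone-rescue outcome class, and
whether a proline is created or removed by the substitution — proline
substitutions were conspicuously refractory to rescue.

``rescue_class`` has three levels because outcomes split into clearly
rescued variants (7), marginal responders, and non-responders; the
marginal/non-responsive split within the 6 non-rescued variants is
recorded per-record with a free-text note.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

RESCUE_CLASSES = ("rescued", "marginal", "non_responsive")
DOMAINS = (
    "ECD", "TMD1", "TMD2", "TMD3", "TMD4", "TMD5", "TMD6", "TMD7", "ECL2", "ECL3",
)

_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with its rescue annotation."""

    label: str
    wild_type: str
    position: int
    substitute: str
    domain: str
    rescue_class: str
    proline_involved: bool
    note: str = ""

    def __post_init__(self) -> None:
        m = _LABEL_RE.match(self.label)
        if not m:
            raise ValueError(f"variant label {self.label!r} does not parse as e.g. D408Y")
        wt, pos, sub = m.group(1), int(m.group(2)), m.group(3)
        if (wt, pos, sub) != (self.wild_type, self.position, self.substitute):
            raise ValueError(
                f"label {self.label!r} inconsistent with fields "
                f"({self.wild_type}, {self.position}, {self.substitute})"
            )
        if self.position <= 0:
            raise ValueError("position must be positive")
        if self.rescue_class not in RESCUE_CLASSES:
            raise ValueError(
                f"rescue_class {self.rescue_class!r} not in {RESCUE_CLASSES}"
            )
        if self.domain not in DOMAINS:
            raise ValueError(f"domain {self.domain!r} not in {DOMAINS}")

    @classmethod
    def from_label(
        cls, label: str, domain: str, rescue_class: str,
        proline_involved: bool, note: str = "",
    ) -> "VariantRecord":
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"variant label {label!r} does not parse as e.g. D408Y")
        return cls(
            label=label, wild_type=m.group(1), position=int(m.group(2)),
            substitute=m.group(3), domain=domain, rescue_class=rescue_class,
            proline_involved=proline_involved, note=note,
        )


def load_variant_table() -> list[VariantRecord]:
    """Load the packaged 13-variant table; labels are unique."""
    with resources.files("fshrdyn.data").joinpath("variants.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = {"label", "domain", "rescue_class", "proline_involved", "note"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table is missing columns: {sorted(missing)}")
    records = [
        VariantRecord.from_label(
            row.label, row.domain, row.rescue_class,
            row.proline_involved.strip().lower() == "true",
            row.note,
        )
        for row in df.itertuples()
    ]
    labels = [r.label for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("variant table contains duplicate labels")
    return records


def count_by(records: list[VariantRecord], fieldname: str) -> dict:
    """Counts of records per value of ``fieldname``; counts sum to len(records)."""
    if records and not hasattr(records[0], fieldname):
        raise AttributeError(f"VariantRecord has no field {fieldname!r}")
    out: dict = {}
    for r in records:
        key = getattr(r, fieldname)
        out[key] = out.get(key, 0) + 1
    return out


def filter_variants(records: list[VariantRecord], predicate) -> list[VariantRecord]:
    """Order-preserving subset of records satisfying ``predicate``."""
    return [r for r in records if predicate(r)]
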