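"""Controlled vocabulary: domain signature accessions -> pipeline tokens.

Two kinds of entries:

* ``pts`` rows map a signature to an enzyme II subunit (IIA/IIB/IIC/IID)
  and a substrate family;
* ``marker`` rows map a signature to a synteny marker type
  (``sigma54``, ``sis``, ``is_element``).

The default vocabulary ships as an editable TSV in ``ptsevo/data``;
product-text regex fallbacks for markers live in a YAML file next to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

SUBUNITS = ("IIA", "IIB", "IIC", "IID")
FAMILIES = (
    "FRU_MAN_SOR",
    "FRU_MANNITOL",
    "GLUCOSE",
    "LACTOSE",
    "GLUCITOL",
    "GALACTITOL",
    "ASCORBATE",
    "UNKNOWN",
)
MARKERS = ("sigma54", "sis", "is_element")


@dataclass(frozen=True)
class SignatureInfo:
    signature_id: str
    label: str
    kind: str  # "pts" | "marker" | "other"
    subunit: str | None = None
    family: str | None = None
    marker: str | None = None


_OTHER = SignatureInfo("", "OTHER", "other")


class Vocabulary:
    """Lookup table from signature accessions to normalized tokens."""

    def __init__(self, entries: list[SignatureInfo],
                 product_patterns: dict[str, str] | None = None) -> None:
        self._by_id = {e.signature_id: e for e in entries}
        self.product_patterns = {
            m: re.compile(pat, re.IGNORECASE)
            for m, pat in (product_patterns or {}).items()
        }

    def lookup(self, signature_id: str) -> SignatureInfo:
        return self._by_id.get(signature_id, _OTHER)

    def label(self, signature_id: str) -> str:
        return self.lookup(signature_id).label

    def pts_signature(self, subunit: str, family: str) -> str:
        """First accession declaring (subunit, family); used by the simulator."""
        for e in self._by_id.values():
            if e.kind == "pts" and e.subunit == subunit and e.family == family:
                return e.signature_id
        raise KeyError(f"no signature for {subunit}/{family}")

    def marker_signature(self, marker: str) -> str:
        for e in self._by_id.values():
            if e.kind == "marker" and e.marker == marker:
                return e.signature_id
        raise KeyError(f"no signature for marker {marker}")

    def marker_of_label(self, label: str) -> str | None:
        for e in self._by_id.values():
            if e.label == label and e.kind == "marker":
                return e.marker
        return None

    def product_matches(self, marker: str, product: str) -> bool:
        pat = self.product_patterns.get(marker)
        return bool(pat and pat.search(product or ""))

    @classmethod
    def from_files(cls, vocab_tsv: str | Path,
                   patterns_yaml: str | Path | None = None) -> "Vocabulary":
        entries = []
        for line in Path(vocab_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"vocabulary row needs 6 columns: {line!r}")
            sig, label, kind, subunit, family, marker = parts
            entries.append(SignatureInfo(
                sig, label, kind,
                subunit if subunit != "-" else None,
                family if family != "-" else None,
                marker if marker != "-" else None,
            ))
        patterns = {}
        if patterns_yaml is not None:
            patterns = yaml.safe_load(Path(patterns_yaml).read_text()) or {}
        return cls(entries, patterns)

    @classmethod
    def default(cls) -> "Vocabulary":
        data = resources.files("ptsevo.data")
        return cls.from_files(
            data / "signature_vocab.tsv",
            data / "marker_patterns.yaml",
        )
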