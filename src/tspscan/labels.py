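"""Parsing of MHC-style tip labels.

Tip labels in curated MHC allele sets follow the IPD convention
``<SpeciesCode><sep><AlleleName>`` where the species code is a four-letter
abbreviation (``Patr`` for chimpanzee, ``Gogo`` for gorilla, ``Mamu`` for
rhesus macaque, ...) or the literal ``HLA`` for human, the separator is
``-`` or ``_``, and the allele name carries the locus and numbering fields
(``B*07:02``) or an accession.  Parsing is total: labels that do not match
the pattern are kept verbatim with species ``unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

__all__ = ["TaxonLabel", "parse_taxon_label", "parse_taxon_labels"]

_LABEL_RE = re.compile(r"^([A-Za-z]{4}|HLA)([-_])(.+)$")


@dataclass(frozen=True)
class TaxonLabel:
    """A parsed tip label.

    ``raw`` is the original string; ``species_code`` is a four-letter code,
    ``HLA``, or ``unknown``; ``allele_name`` is the remainder of the label.
    For labels that matched the expected pattern,
    ``species_code + separator + allele_name == raw``.
    """

    raw: str
    species_code: str
    allele_name: str
    separator: str = ""
    group: Optional[str] = None

    @property
    def matched(self) -> bool:
        return self.species_code != "unknown"

    def reserialize(self) -> str:
        if not self.matched:
            return self.raw
        return f"{self.species_code}{self.separator}{self.allele_name}"

    def with_group(self, group: Optional[str]) -> "TaxonLabel":
        return replace(self, group=group)


def parse_taxon_label(raw: str, species_table: Optional[Iterable[str]] = None) -> TaxonLabel:
    """Parse one tip label.

    If ``species_table`` is given, a prefix is only accepted as a species
    code when it appears in the table; otherwise any four-letter prefix (or
    ``HLA``) followed by ``-`` or ``_`` is accepted.  Never raises on
    well-formed text.
    """
    m = _LABEL_RE.match(raw)
    if m:
        code, sep, allele = m.groups()
        if species_table is None or code in set(species_table):
            return TaxonLabel(raw=raw, species_code=code, allele_name=allele, separator=sep)
    return TaxonLabel(raw=raw, species_code="unknown", allele_name=raw, separator="")


def parse_taxon_labels(raws: Iterable[str], species_table: Optional[Iterable[str]] = None) -> list[TaxonLabel]:
    table = None if species_table is None else set(species_table)
    return [parse_taxon_label(r, table) for r in raws]
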