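"""Catalogues of conserved NCLDV orthologous genes (NCVOGs) used across the pipeline.

Three marker sets drive genome selection, contamination screening and quality
estimation, plus a small set of long, conserved proteins used to flag
assembly-level duplicates during dereplication:

* ``CORE5`` — the five hallmark genes (DNA polymerase B, D5 helicase-primase,
  packaging ATPase, superfamily-II helicase, VLTF3-like transcription factor)
  used to admit genomes into the species tree.
* ``DUP16`` — sixteen NCVOGs that are near-universally low-copy across
  published NCLDV genomes; their aggregate copy/unique ratio is the
  duplication ratio used as a contamination proxy.
* ``QUALITY20`` — twenty conserved, putatively vertically-inherited NCVOGs
  whose presence and copy-number profile, compared against a superclade
  baseline, yields completeness and contamination tiers.
* ``DEREP6`` — the six NCVOGs with the longest average protein products;
  full-length 100 %-identity hits on any of them between genomes of the same
  ANI cluster mark potential duplicates.

The quality set's published membership is supplementary material; the default
shipped here comprises the nineteen NCVOGs named in the pipeline description
plus the DNA-directed RNA polymerase subunit (NCVOG0271), and is overridable
wherever it is consumed.
"""

from __future__ import annotations

CORE5: frozenset[str] = frozenset(
    {"NCVOG0038", "NCVOG0023", "NCVOG0249", "NCVOG0076", "NCVOG0262"}
)

DUP16: frozenset[str] = frozenset(
    {
        "NCVOG0035",
        "NCVOG0036",
        "NCVOG0038",
        "NCVOG0052",
        "NCVOG0059",
        "NCVOG0211",
        "NCVOG0249",
        "NCVOG0256",
        "NCVOG0262",
        "NCVOG1060",
        "NCVOG1088",
        "NCVOG1115",
        "NCVOG1117",
        "NCVOG1122",
        "NCVOG1127",
        "NCVOG1192",
    }
)

DEREP6: frozenset[str] = frozenset(
    {"NCVOG0022", "NCVOG0023", "NCVOG0038", "NCVOG0059", "NCVOG0256", "NCVOG1117"}
)

QUALITY20: frozenset[str] = frozenset(
    DUP16 | CORE5 | {"NCVOG0022", "NCVOG0271"}
)

#: Copy-number caps: a genome fails if it encodes strictly more copies than this.
COPY_NUMBER_CAPS: dict[str, int] = {
    "NCVOG0023": 20,
    "NCVOG0038": 4,
    "NCVOG0076": 12,
    "NCVOG0249": 7,
    "NCVOG0262": 4,
}

#: Genomes with a DUP16 duplication ratio strictly above this are excluded.
MAX_DUPLICATION_RATIO: float = 3.0
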