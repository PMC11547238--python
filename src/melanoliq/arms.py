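"""Autosomal chromosome-arm table (GRCh38).

The aneuploidy assay reports read counts per chromosome arm for the 39
autosomal arms conventionally used in LINE-1 amplicon aneuploidy screens:
chr1-22 p and q, excluding the five acrocentric short arms (13p, 14p, 15p,
21p, 22p), which carry almost no uniquely mappable sequence.

Arm lengths (Mb, approximate, from GRCh38 cytoband boundaries) are bundled
statically so that baseline arm proportions can be derived without any
external resource.  Only the *relative* lengths matter downstream.
"""

from __future__ import annotations

import numpy as np

# (arm, length in Mb); p/q split at the centromere midpoint.
_ARM_LENGTHS_MB: list[tuple[str, float]] = [
    ("1p", 123.4), ("1q", 125.5),
    ("2p", 93.9), ("2q", 148.3),
    ("3p", 90.9), ("3q", 107.4),
    ("4p", 50.0), ("4q", 140.2),
    ("5p", 48.8), ("5q", 132.7),
    ("6p", 59.8), ("6q", 111.0),
    ("7p", 60.1), ("7q", 99.2),
    ("8p", 45.2), ("8q", 99.9),
    ("9p", 43.0), ("9q", 95.4),
    ("10p", 39.8), ("10q", 94.0),
    ("11p", 53.4), ("11q", 81.7),
    ("12p", 35.5), ("12q", 97.8),
    ("13q", 96.7),
    ("14q", 89.8),
    ("15q", 83.0),
    ("16p", 36.8), ("16q", 53.5),
    ("17p", 25.1), ("17q", 58.2),
    ("18p", 18.5), ("18q", 61.9),
    ("19p", 26.2), ("19q", 32.4),
    ("20p", 28.1), ("20q", 36.3),
    ("21q", 34.7),
    ("22q", 35.8),
]

#: The 39 autosomal arms, in karyotype order.
AUTOSOMAL_ARMS: tuple[str, ...] = tuple(a for a, _ in _ARM_LENGTHS_MB)

ARM_LENGTHS: dict[str, float] = dict(_ARM_LENGTHS_MB)


def baseline_arm_proportions(arms: tuple[str, ...] | list[str] = AUTOSOMAL_ARMS) -> np.ndarray:
    """Expected fraction of reads per arm for a diploid genome.

    Proportional to arm length, i.e. reads are assumed uniform over the
    mappable genome.  Returns an array aligned with ``arms`` summing to 1.
    """
    lengths = np.array([ARM_LENGTHS[a] for a in arms], dtype=float)
    return lengths / lengths.sum()
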