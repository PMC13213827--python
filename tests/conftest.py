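"""Shared fixtures: a handcrafted ATP complex and small builders.

The ATP fixture is written record by record so tests can count its atoms
independently of any parser.
"""

from __future__ import annotations

import numpy as np
import pytest

# ATP heavy atoms (PDB chemical component naming): 3 P, 13 O, 10 C, 5 N = 31.
ATP_ATOMS = [
    ("PG", "P"), ("O1G", "O"), ("O2G", "O"), ("O3G", "O"),
    ("PB", "P"), ("O1B", "O"), ("O2B", "O"), ("O3B", "O"), ("O3A", "O"),
    ("PA", "P"), ("O1A", "O"), ("O2A", "O"), ("O5'", "O"),
    ("C5'", "C"), ("C4'", "C"), ("O4'", "O"), ("C3'", "C"), ("O3'", "O"),
    ("C2'", "C"), ("O2'", "O"), ("C1'", "C"),
    ("N9", "N"), ("C8", "C"), ("N7", "N"), ("C5", "C"), ("C6", "C"),
    ("N6", "N"), ("N1", "N"), ("C2", "C"), ("N3", "N"), ("C4", "C"),
]


def atom_line(rec, serial, name, element, res, chain, num, x, y, z):
    if len(element) == 1 and len(name) <= 3:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{rec:<6s}{serial:>5d} {name_f} {res:<3s} {chain}{num:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}          {element:>2s}"
    )


def build_pdb(
    sequence: str = "AGS",
    het_atoms=None,
    het_code: str = "ATP",
    extra_header: list[str] | None = None,
    link_lines: list[str] | None = None,
    with_water: bool = False,
    resolution: float = 1.80,
    structure_id: str = "1ABC",
):
    """Minimal but column-correct PDB text: one chain plus one hetero-group."""
    from bioactlink.fixtures import AA1TO3, _seqres_lines

    lines = [
        f"HEADER    TEST COMPLEX                            01-JAN-05   {structure_id}",
        "EXPDTA    X-RAY DIFFRACTION",
        f"REMARK   2 RESOLUTION.{resolution:8.2f} ANGSTROMS.",
        "REMARK   3   R VALUE            (WORKING SET) : 0.180",
        "REMARK   3   FREE R VALUE                     : 0.210",
    ]
    lines.extend(extra_header or [])
    lines.extend(_seqres_lines("A", sequence))
    lines.extend(link_lines or [])
    serial = 1
    for i, aa in enumerate(sequence):
        lines.append(atom_line("ATOM", serial, "CA", "C", AA1TO3[aa], "A", i + 1,
                               3.8 * i, 0.0, 0.0))
        serial += 1
    if het_atoms:
        for k, (name, element) in enumerate(het_atoms):
            lines.append(atom_line("HETATM", serial, name, element, het_code, "A", 101,
                                   float(k % 6), 3.0 + (k // 6), 0.0))
            serial += 1
    if with_water:
        lines.append(atom_line("HETATM", serial, "O", "O", "HOH", "A", 201,
                               30.0, 30.0, 30.0))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def atp_pdb():
    return build_pdb(het_atoms=ATP_ATOMS, with_water=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
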