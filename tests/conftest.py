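import numpy as np
import pytest

from riborigid.synthetic import make_quadruple, make_toy_aptamer

MINIMAL_PDB = """\
ATOM      1  P     G A  15      -2.0   0.0   0.0  1.00  0.00           P
ATOM      2  C1'   G A  15       0.0   0.0   0.0  1.00  0.00           C
ATOM      3  N9    G A  15       1.4   0.0   0.0  1.00  0.00           N
END
"""

MG_WATER_PDB = """\
HETATM    1 MG    MG A 101       0.0   0.0   0.0  1.00  0.00          MG
HETATM    2  O   HOH A 201       2.1   0.0   0.0  1.00  0.00           O
HETATM    3  O   HOH A 202      -2.1   0.0   0.0  1.00  0.00           O
HETATM    4  O   HOH A 203       0.0   2.1   0.0  1.00  0.00           O
HETATM    5  O   HOH A 204       0.0  -2.1   0.0  1.00  0.00           O
HETATM    6  O   HOH A 205       0.0   0.0   2.1  1.00  0.00           O
HETATM    7  O   HOH A 206       0.0   0.0  -2.1  1.00  0.00           O
END
"""


def three_nt_pdb() -> str:
    """Minimal 3-nucleotide chain carrying the backbone atoms needed for
    the inter-residue O3'-P links."""
    lines = []
    serial = 1
    for k, (resseq, base) in enumerate([(15, "G"), (16, "A"), (17, "C")]):
        z = 6.0 * k
        for name, el, (x, y) in [("P", "P", (0.0, 0.0)),
                                 ("O5'", "O", (1.2, 0.5)),
                                 ("C1'", "C", (2.5, 1.0)),
                                 ("O3'", "O", (0.5, 2.0))]:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {base:>3s} A{resseq:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {el:>2s}")
            serial += 1
    # place each O3' near the next residue's P
    fixed = []
    for line in lines:
        if " O3' " in line:
            resseq = int(line[22:26])
            z = 6.0 * (resseq - 15) + 5.5
            line = line[:46] + f"{z:8.3f}" + line[54:]
        fixed.append(line)
    return "\n".join(fixed) + "\nEND\n"


@pytest.fixture(scope="session")
def toy():
    return make_toy_aptamer()


@pytest.fixture(scope="session")
def quadruple_wt():
    return make_quadruple(mutant=False)


@pytest.fixture(scope="session")
def quadruple_mut():
    return make_quadruple(mutant=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
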