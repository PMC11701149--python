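import numpy as np
import pytest

from splicecall import catalog_from_counts, make_abo_like_fixture

#: codon table used by test oracles, written independently of the package's
#: translation path (which goes through Biopython)
ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> tuple[str, bool]:
    """Independent codon walk: (protein to first stop, stop_found)."""
    protein = []
    for i in range(0, len(seq) - 2, 3):
        aa = ORACLE_CODONS[seq[i:i + 3]]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def random_windows(rng: np.random.Generator, n: int) -> list[str]:
    """Random GT donor windows."""
    bases = np.array(list("ACGT"))
    out = []
    for _ in range(n):
        w = bases[rng.integers(0, 4, size=9)]
        w[3], w[4] = "G", "T"
        out.append("".join(w))
    return out


@pytest.fixture(scope="session")
def paper_catalog():
    """Partial catalog holding the worked-example donor window."""
    return catalog_from_counts({"CAGGTGAGG": 2562}, total_sites=189249, partial=True)


@pytest.fixture(scope="session")
def abo_fixture():
    return make_abo_like_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
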