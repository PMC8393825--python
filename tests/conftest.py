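"""Shared fixtures: variable systems and the published table rows."""

import re

import pytest

from rabn import VariableSystem
from rabn.bn import Dag
from rabn.core import IndependenceStatement


@pytest.fixture(scope="session")
def sys2():
    return VariableSystem(("A", "B"))


@pytest.fixture(scope="session")
def sys3():
    return VariableSystem(("A", "B", "C"))


@pytest.fixture(scope="session")
def sys4():
    return VariableSystem(("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def sysz():
    return VariableSystem(("A", "B", "C", "Z"))


_FACTOR = re.compile(r"p\((\w)(?:\|(\w+))?\)")


def dag_from_factorization(text: str, system: VariableSystem) -> Dag:
    """Build the DAG named by a factorization string like p(A|CD)p(C)..."""
    edges = []
    for child, parents in _FACTOR.findall(text):
        for p in parents or "":
            edges.append((p, child))
    return Dag(system, edges)


def factor_terms(text: str):
    return frozenset(
        (child, frozenset(parents or "")) for child, parents in _FACTOR.findall(text)
    )


def parse_statements(text: str) -> frozenset:
    """Parse a printed independence list like "(A ⊥ B, C | D), (B ⊥ C | D)"."""
    out = set()
    if text.strip() == "none":
        return frozenset()
    for body in re.findall(r"\(([^()]*)\)", text):
        body = body.replace(" ", "").replace("⟂", "⊥")
        if "|" in body:
            sides, given = body.split("|")
            given = [v for part in given.split(",") for v in part]
        else:
            sides, given = body, []
        left, right = sides.split("⊥")
        split = lambda s: [v for part in s.split(",") for v in part]
        out.add(IndependenceStatement(split(left), split(right), given))
    return frozenset(out)


# The 20 published representatives of the four-variable BN specific-graph
# lattice: (name, extended notation, factorization, minimal independence list).
BN_TABLE_ROWS = [
    ("BN1", "ABCD", "p(B|A)p(A)p(C|AB)p(D|ABC)", "none"),
    ("BN2", "ACD:BCD", "p(A|CD)p(C)p(B|CD)p(D|C)", "(A ⊥ B | C, D)"),
    ("BN3", "ABCD_A:B_", "p(C|AB)p(A)p(B)p(D|ABC)", "(A ⊥ B)"),
    ("BN4", "ABCD_AC:BC_", "p(A|C)p(C)p(B|C)p(D|ABC)", "(A ⊥ B | C)"),
    ("BN5", "BCD:AD", "p(A|D)p(D)p(B|CD)p(C|D)", "(A ⊥ B, C | D)"),
    ("BN6", "ABCD_BC:A_", "p(B|C)p(C)p(D|ABC)p(A)", "(A ⊥ B, C)"),
    ("BN7", "BCD:ABD_A:B_", "p(C|BD)p(B)p(D|AB)p(A)", "(A ⊥ B), (A ⊥ C | B, D)"),
    ("BN8", "ACD_C:D_:BCD_C:D_", "p(A|CD)p(C)p(D)p(B|CD)", "(C ⊥ D), (A ⊥ B | C, D)"),
    ("BN9", "ABD:ABC_AC:BC_", "p(A|C)p(C)p(B|C)p(D|AB)", "(A ⊥ B | C), (C ⊥ D | A, B)"),
    ("BN10", "BCD:A", "p(B|C)p(C)p(D|BC)p(A)", "(A ⊥ B, C, D)"),
    ("BN11", "AD:BD:CD", "p(A|D)p(D)p(B|D)p(C|D)", "(A ⊥ B, C | D), (B ⊥ C | D)"),
    ("BN12", "ABCD_A:B:C_", "p(D|ABC)p(A)p(B)p(C)", "(A ⊥ B, C), (B ⊥ C)"),
    ("BN13", "ACD_A:C_:BD", "p(B|D)p(D|AC)p(A)p(C)", "(A ⊥ C), (B ⊥ A, C | D)"),
    ("BN14", "AD:BC:BD", "p(A|D)p(D)p(B|D)p(C|B)", "(A ⊥ B | D), (C ⊥ A, D | B)"),
    ("BN15", "ABD_A:B_:BC", "p(C|B)p(B)p(D|AB)p(A)", "(A ⊥ B, C), (C ⊥ D | A, B)"),
    ("BN16", "BD:CD:A", "p(B|D)p(D)p(C|D)p(A)", "(B ⊥ C | D), (A ⊥ B, C, D)"),
    ("BN17", "BCD_B:C_:A", "p(D|BC)p(B)p(C)p(A)", "(B ⊥ C), (A ⊥ B, C, D)"),
    ("BN18", "AD:BC", "p(C|B)p(B)p(D|A)p(A)", "(A, D ⊥ B, C)"),
    ("BN19", "CD:A:B", "p(D|C)p(C)p(A)p(B)", "(B ⊥ C, D), (A ⊥ B, C, D)"),
    ("BN20", "A:B:C:D", "p(A)p(B)p(C)p(D)", "(A ⊥ B, C, D), (B ⊥ C, D), (C ⊥ D)"),
]

# The ten equivalent RA-BN general-graph pairs, by their published example
# specific graphs (RA notation and shared minimal independence list).
EQUIVALENT_PAIR_ROWS = [
    ("rho1", "ABCD", "none"),
    ("rho2", "ACD:BCD", "(A ⊥ B | C, D)"),
    ("rho3", "BCD:AD", "(A ⊥ B, C | D)"),
    ("rho5", "BCD:A", "(A ⊥ B, C, D)"),
    ("rho6", "AD:BD:CD", "(A ⊥ B, C | D), (B ⊥ C | D)"),
    ("rho7", "AD:BC:BD", "(A ⊥ B | D), (C ⊥ A, D | B)"),
    ("rho8", "BD:CD:A", "(B ⊥ C | D), (A ⊥ B, C, D)"),
    ("rho9", "AD:BC", "(A, D ⊥ B, C)"),
    ("rho10", "CD:A:B", "(B ⊥ C, D), (A ⊥ B, C, D)"),
    ("rho11", "A:B:C:D", "(A ⊥ B, C, D), (B ⊥ C, D), (C ⊥ D)"),
]

# Retained BN directed-system graphs and their RA equivalents (dv = Z).
RA_EQUIVALENT_ROWS = [
    ("BN7", "ABZ_A:B_:BCZ", "ABZ:BCZ"),
    ("BN11", "AZ:BZ:CZ", "AZ:BZ:CZ"),
    ("BN12", "ABCZ_A:B:C_", "ABCZ"),
    ("BN13", "ACZ_A:C_:BZ", "ACZ:BZ"),
    ("BN16", "BZ:CZ:A", "BZ:CZ:A"),
    ("BN17", "BCZ_B:C_:A", "ABC:BCZ"),
    ("BN19", "CZ:A:B", "ABC:CZ"),
    ("BN20", "A:B:C:Z", "ABC:Z"),
]
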