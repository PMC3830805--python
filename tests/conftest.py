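import numpy as np
import pytest

from hapnetrec import encode_binary, fig1_fixture, synthetic_abo54_representatives
from hapnetrec.model import BinaryMatrix, Site


@pytest.fixture(scope="session")
def fig1():
    matrix, truth = fig1_fixture()
    return matrix, truth


@pytest.fixture(scope="session")
def fig1_binary(fig1):
    matrix, _ = fig1
    return encode_binary(matrix)


@pytest.fixture(scope="session")
def abo54():
    return synthetic_abo54_representatives()


@pytest.fixture(scope="session")
def abo54_binary(abo54):
    return encode_binary(abo54)


def make_binary(rows: dict[str, str], outgroup: str) -> BinaryMatrix:
    """Build a BinaryMatrix from name -> '0101...' strings (test helper)."""
    names = list(rows)
    L = len(next(iter(rows.values())))
    data = np.array([[int(c) for c in rows[n]] for n in names], dtype=np.int8)
    return BinaryMatrix(
        names=names,
        data=data,
        sites=[Site(index=j + 1) for j in range(L)],
        allele_map=[("A", "G")] * L,
        outgroup_id=outgroup,
    )
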