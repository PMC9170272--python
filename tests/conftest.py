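import numpy as np
import pytest

from lingsync import CategoryDictionary, ProfileMatrix, load_dictionary

# Toy category dictionary covering every category the default summary
# variable compositions reference, plus enough words for token streams.
TOY_DIC = """\
%
1\tarticle
2\tpreposition
3\tpronoun
4\tauxverb
5\tconjunction
6\tadverb
7\tnegation
8\twe
9\tyou
10\ttentative
11\ti
12\tthird_person
13\texclusive
14\tnegemo
15\tmotion
16\tposemo
%
the\t1
a\t1
an\t1
of\t2
in\t2
to\t2
it\t3
it's\t3
she\t3 12
he\t3 12
they\t3 12
i\t3 11
we\t3 8
you\t3 9
is\t4
was\t4
and\t5
but\t5 13
very\t6
really\t6
not\t7
never\t7
maybe\t10
perhaps\t10
tentativ*\t10
except\t13
without\t13
hurt\t14
ugly\t14
nasty\t14
walk\t15
go\t15
move\t15
love\t16
nice\t16
sweet\t16
happ*\t16
"""


@pytest.fixture(scope="session")
def toy_dic_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("dic") / "toy.dic"
    path.write_text(TOY_DIC, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def toy_dictionary(toy_dic_path) -> CategoryDictionary:
    return load_dictionary(toy_dic_path)


@pytest.fixture()
def small_matrix() -> ProfileMatrix:
    """A 3-session dyad matrix with distinct, non-degenerate columns."""
    rng = np.random.default_rng(7)
    labels = tuple(
        (role, s) for role in ("client", "therapist") for s in (1, 2, 3)
    )
    values = 50 + 10 * rng.standard_normal((6, 4))
    return ProfileMatrix("TOY", labels, values)


def blob_matrix(
    centers: np.ndarray,
    rows_per_blob: int,
    noise_sd: float = 0.5,
    seed: int = 0,
    dyad_id: str = "BLOBS",
) -> ProfileMatrix:
    """Well-separated Gaussian blobs as a labelled profile matrix."""
    rng = np.random.default_rng(seed)
    values = np.vstack(
        [c + noise_sd * rng.standard_normal((rows_per_blob, 4)) for c in centers]
    )
    n = len(values)
    half = n // 2
    labels = tuple(
        [("client", s) for s in range(1, half + 1)]
        + [("therapist", s) for s in range(1, n - half + 1)]
    )
    return ProfileMatrix(dyad_id, labels, values)
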