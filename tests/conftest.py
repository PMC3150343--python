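import numpy as np
import pandas as pd
import pytest

from rankgrade import ExpressionMatrix, ExpressionProfile, GradeSignature


@pytest.fixture
def toy_sig():
    """3 up-in-G3 + 2 up-in-G1 probes, for hand-computed examples."""
    return GradeSignature(name="toy3x2", g3_up=frozenset({"p1", "p2", "p3"}), g1_up=frozenset({"p4", "p5"}))


@pytest.fixture
def hand_profile():
    """10-probe profile with distinct values; ranks are 6,4,10,2,8,3,5,7,9,1.

    Hand-worked mean ranks under ``toy_sig``: g3_up {p1,p2,p3} -> (6+4+10)/3
    = 20/3; g1_up {p4,p5} -> (2+8)/2 = 5; so the call is G3 with score
    (20/3 - 5)/10 = 1/6.
    """
    probes = [f"p{i}" for i in range(1, 11)]
    values = [5.0, 3.0, 9.0, 1.0, 7.0, 2.0, 4.0, 6.0, 8.0, 0.0]
    return ExpressionProfile(sample_id="hand", probe_ids=probes, values=np.array(values))


def make_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


@pytest.fixture
def rank_oracle():
    """Pairwise-comparison rank oracle: rank_i = 1 + #{v_j < v_i} + 0.5*#{j!=i: v_j = v_i}."""

    def oracle(values):
        v = np.asarray(values, dtype=float)
        less = (v[None, :] < v[:, None]).sum(axis=1)
        equal = (v[None, :] == v[:, None]).sum(axis=1) - 1
        return 1.0 + less + 0.5 * equal

    return oracle
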