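import numpy as np
import pytest

from roughprog.decision_table import AttributeSpec, DecisionTable
from roughprog.synthetic_data import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def random_table(rng: np.random.Generator, n_obj: int | None = None,
                 n_attr: int | None = None, n_classes: int = 2,
                 criteria_only: bool = False) -> DecisionTable:
    """Small random decision table with mixed plain attributes and
    criteria, for brute-force oracle comparisons."""
    n_obj = n_obj or int(rng.integers(2, 13))
    n_attr = n_attr or int(rng.integers(1, 5))
    schema = []
    for j in range(n_attr):
        size = int(rng.integers(2, 4))
        if criteria_only:
            role = "gain_criterion"
        else:
            role = ["attribute", "gain_criterion", "cost_criterion"][
                int(rng.integers(0, 3))
            ]
        domain = tuple(f"v{k}" for k in range(size))
        schema.append(AttributeSpec(f"a{j}", role, domain))
    decision_domain = tuple(f"d{k}" for k in range(n_classes))
    schema.append(AttributeSpec("dec", "decision", decision_domain))
    objects = [f"o{i}" for i in range(n_obj)]
    values = {}
    for o in objects:
        row = {s.name: s.domain[int(rng.integers(0, len(s.domain)))]
               for s in schema}
        values[o] = row
    return DecisionTable(objects, schema, values)
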