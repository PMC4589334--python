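import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cshairpin.io import NUCLEI, Dataset, Fragment, Label, ResidueShiftRow

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_fragment(
    fragment_id: str,
    label: Label,
    shifts_per_residue: list[dict],
    protein_id: str = "prot1",
    sequence: str | None = None,
) -> Fragment:
    """Build a fragment from a list of per-residue shift dicts; any nucleus
    absent from a dict is recorded as missing."""
    seq = sequence or "A" * len(shifts_per_residue)
    rows = [
        ResidueShiftRow(
            protein_id,
            fragment_id,
            i + 1,
            seq[i],
            {m: s.get(m) for m in NUCLEI},
        )
        for i, s in enumerate(shifts_per_residue)
    ]
    return Fragment(fragment_id, protein_id, label, rows)


def constant_fragment(
    fragment_id: str, label: Label, length: int, base: float = 50.0
) -> Fragment:
    """Fragment whose every residue carries the same six shifts."""
    shifts = {m: base + j for j, m in enumerate(NUCLEI)}
    return make_fragment(fragment_id, label, [dict(shifts)] * length)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two complete fragments, one per class (3 + 4 residues)."""
    rng = np.random.default_rng(42)

    def rand_rows(n):
        return [
            {m: float(rng.normal(50, 5)) for m in NUCLEI} for _ in range(n)
        ]

    return Dataset(
        [
            make_fragment("h1", Label.HAIRPIN, rand_rows(3)),
            make_fragment("n1", Label.NOT_HAIRPIN, rand_rows(4)),
        ]
    )


@pytest.fixture
def random_dataset() -> Dataset:
    """20 fragments per class with mild separation; no missingness."""
    from cshairpin.synthetic import default_config, generate_dataset

    cfg = default_config(2.0, n_hairpin=20, n_not=20, seed=7)
    data, _ = generate_dataset(cfg)
    return data
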