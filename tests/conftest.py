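import numpy as np
import pytest

from covscreen.aggregate import SiteKey, SiteQuant
from covscreen.io_model import Role, SampleMeta


@pytest.fixture
def single_dose_meta():
    """16 DMSO controls + 4 treated replicates of one compound at 50 uM."""
    meta = [
        SampleMeta(sample_id=f"C{i:02d}", role=Role.control, replicate_index=i)
        for i in range(1, 17)
    ]
    meta += [
        SampleMeta(
            sample_id=f"T{j}",
            role=Role.treated,
            compound_id="PP01",
            concentration_um=50.0,
            replicate_index=j,
        )
        for j in range(1, 5)
    ]
    return meta


def make_quant(
    intensities: dict[str, float],
    accession: str = "P1",
    sequence: str = "ACDEFGK",
    dtb_positions: tuple[int, ...] = (2,),
    residue_index: int | None = 2,
    **flags,
) -> SiteQuant:
    q = SiteQuant(
        protein_accession=accession,
        stripped_sequence=sequence,
        dtb_positions=dtb_positions,
        other_mods=(),
        dtb_count=len(dtb_positions),
        intensity_by_sample=dict(intensities),
        site=SiteKey(accession, residue_index) if residue_index else None,
    )
    for k, v in flags.items():
        setattr(q, k, v)
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(42)
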