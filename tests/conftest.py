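import numpy as np
import pytest

from pssearch.io_formats import ProteinRecord, ResidueProfile
from pssearch.pss_core import PermissiveStretch
from pssearch.fixtures import ProfileSpec, simulate_profile


@pytest.fixture
def simple_profile() -> ResidueProfile:
    """Ten residues with hand-picked RSAs and a coil run at 4..6."""
    rsa = np.array([0.1, 0.4, 0.9, 0.2, 0.8, 0.7, 0.3, 0.5, 0.6, 0.2])
    ss = np.zeros((10, 3))
    ss[:, 0] = 1.0
    ss[3:6] = [0.0, 0.0, 1.0]
    return ResidueProfile("prot", rsa, ss)


def separated_loops_dataset(n_proteins: int = 10, length: int = 300,
                            loop: tuple[int, int] = (140, 160),
                            loop_rsa: float = 0.9, core_rsa: float = 0.1,
                            stretches_per_protein: int = 3, span: int = 4):
    """Proteome where every stretch sits on a high-RSA loop in a low-RSA
    background; no shuffled placement set can reach the observed mean."""
    proteome, stretches = [], []
    for k in range(n_proteins):
        prof = simulate_profile(
            ProfileSpec(length=length, loop_regions=(loop,),
                        rsa_loop_mean=loop_rsa, rsa_core_mean=core_rsa,
                        rsa_sd=0.0, seed=k),
            protein_id=f"p{k}")
        proteome.append((ProteinRecord(f"p{k}", "A" * length), prof))
        for j in range(stretches_per_protein):
            s = loop[0] + 2 + j * (span + 1)
            stretches.append(PermissiveStretch(f"p{k}", s, s + span, label="I"))
    return proteome, stretches
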