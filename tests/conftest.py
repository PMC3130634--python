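import numpy as np
import pytest

from hydsel import eppcr, nullmodel, synthdata
from hydsel.seqcore import ChargeScheme, CodingSequence


@pytest.fixture(scope="session")
def scheme() -> ChargeScheme:
    return ChargeScheme.default()


@pytest.fixture(scope="session")
def summary():
    """Emulated mutant summary: parent CDS + 23 variants + domain map."""
    return synthdata.generate_mutant_summary(seed=0)


@pytest.fixture(scope="session")
def uniform_spectrum() -> eppcr.MutationSpectrum:
    return eppcr.MutationSpectrum.uniform()


@pytest.fixture(scope="session")
def toy_cds() -> CodingSequence:
    # 10 codons, mixed composition, no internal stops
    return CodingSequence(id="toy", nt="ATG" + "AAACGTGGCTTACTGCCAGAT" + "GCGTAA")


@pytest.fixture(scope="session")
def null_batch12(summary, uniform_spectrum) -> nullmodel.NullDistribution:
    """Shared selection-free null: batch 12, 10^4 replicate batches."""
    return nullmodel.build_null(
        summary.parent, uniform_spectrum, batch_size=12, n_replicates=10_000, seed=11
    )


@pytest.fixture(scope="session")
def trial_batches(summary, uniform_spectrum) -> nullmodel.NullDistribution:
    """1000 independent batches from the same null process (as 'observations')."""
    return nullmodel.build_null(
        summary.parent, uniform_spectrum, batch_size=12, n_replicates=1000, seed=77
    )
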