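import numpy as np
import pytest

from evophys import GeneModel, ODTrace, VariantRecord


@pytest.fixture
def exponential_trace():
    """Noiseless exponential trace: mu = 0.3/h from t = 0, 5-min sampling."""
    t = np.arange(0, 80.0001, 5 / 60)
    return ODTrace(well="exp", times=t, od=0.02 * np.exp(0.3 * t))


@pytest.fixture
def piecewise_trace():
    """Flat at 0.02 until t=8, exponential mu=0.4 over [8,14], plateau after."""
    t = np.arange(0, 20.0001, 5 / 60)
    od = np.where(t < 8, 0.02, np.where(t <= 14, 0.02 * np.exp(0.4 * (t - 8)),
                                        0.02 * np.exp(0.4 * 6)))
    return ODTrace(well="piecewise", times=t, od=od)


@pytest.fixture
def toy_genome():
    """A 30-bp contig with one forward-strand gene ATG GCA TAA at 1..9."""
    genome = {"chr": "ATGGCATAA" + "ACGTACGTACGTACGTACGTA"}
    genes = [GeneModel(gene="g1", contig="chr", start=1, end=9, strand="+",
                       product="toy")]
    return genome, genes


def make_variant(pos, ref, alt, frequency=1.0, depth=50, isolate="iso",
                 contig="chr"):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                         frequency=frequency, depth=depth, isolate=isolate)
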