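import textwrap

import numpy as np
import pytest

from aimkit.model import GenotypeMatrix, SamplePanel, VariantRecord
from aimkit.simulate import PopulationSpec, SimulationConfig, SpikeSpec, simulate


@pytest.fixture
def write_text(tmp_path):
    """Write dedented text to a temp file and return its path."""

    def _write(name: str, content: str):
        path = tmp_path / name
        path.write_text(textwrap.dedent(content).lstrip("\n"))
        return path

    return _write


TOY_VCF = """
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=X>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|1\t./.\t1|1
1\t300\trs3\tG\tA,T\t.\t.\t.\tGT\t0/2\t1/2\t0/0
X\t400\trs4\tT\tC\t.\t.\t.\tGT\t0\t0/1\t1
"""


@pytest.fixture
def toy_vcf(write_text):
    return write_text("toy.vcf", TOY_VCF)


@pytest.fixture
def toy_panel(write_text):
    return write_text(
        "toy.panel",
        """
        sample\tpop\tsuper_pop\tgender
        S1\tYRI\tAFR\tmale
        S2\tCEU\tEUR\tfemale
        S3\tYRI\tAFR\tmale
        """,
    )


def make_matrix(genotypes, variants=None, samples=None, phased=None):
    """Build a GenotypeMatrix from a nested list of (a, b) tuples
    (samples x variants); None means a missing call."""
    n_s = len(genotypes)
    n_v = len(genotypes[0]) if n_s else 0
    if variants is None:
        variants = [
            VariantRecord("1", 100 * (j + 1), f"v{j + 1}", "A", ("G",))
            for j in range(n_v)
        ]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_s)]
    alleles = np.full((n_s, n_v, 2), -1, dtype=np.int16)
    for i, row in enumerate(genotypes):
        for j, call in enumerate(row):
            if call is not None:
                alleles[i, j] = call
    return GenotypeMatrix(variants, samples, alleles, phased=phased)


@pytest.fixture
def two_pop_sim():
    """Small two-population Balding-Nichols dataset with fixed seed."""
    cfg = SimulationConfig(
        populations=(
            PopulationSpec("P1", 50, 0.1),
            PopulationSpec("P2", 50, 0.1),
        ),
        n_markers=300,
        seed=20240101,
    )
    return simulate(cfg)


@pytest.fixture
def spike_sim():
    """Three source groups + one reference group with spiked AIMs."""
    pops = tuple(
        PopulationSpec(lb, 60, 0.01, super_pop="AFR")
        for lb in ("AFR1", "AFR2", "AFR3")
    ) + (PopulationSpec("EUR1", 60, 0.01, super_pop="EUR"),)
    cfg = SimulationConfig(
        populations=pops,
        n_markers=600,
        seed=99,
        spike=SpikeSpec(
            count=100, freqs={"AFR1": 0.9, "AFR2": 0.9, "AFR3": 0.9, "EUR1": 0.1}
        ),
    )
    return simulate(cfg)
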