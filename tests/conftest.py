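"""Shared fixtures: tiny hand-built matrices and a small emitted dataset."""
import numpy as np
import pandas as pd
import pytest

from domestiscan import synthetic_data as sd
from domestiscan import variant_io as vio


def make_gm(dosages, samples=None, chrom="chr1", start_pos=100, spacing=50):
    """GenotypeMatrix from a (samples x sites) dosage array, SNP sites."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_sites),
            "ref": "A",
            "alt": "G",
            "vclass": "snp",
        }
    )
    return vio.GenotypeMatrix(samples, sites, dosages)


@pytest.fixture(scope="session")
def small_sim_config():
    return sd.SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length=100_000,
        n_sites=1_500,
        n_genes=10,
        n_indels=12,
        sweep_intervals=[sd.SweepSpec("chr1", 20_000, 30_000, "seed", 8.0)],
    )


@pytest.fixture(scope="session")
def emitted_dataset(tmp_path_factory, small_sim_config):
    outdir = tmp_path_factory.mktemp("simdata")
    paths = sd.emit_dataset(small_sim_config, outdir)
    return {"cfg": small_sim_config, **paths}


@pytest.fixture(scope="session")
def ingested(emitted_dataset):
    gm = vio.read_vcf(emitted_dataset["vcf"])
    grouping = vio.read_grouping(emitted_dataset["groups"], gm)
    genes = vio.read_gff(emitted_dataset["gff"])
    reference = vio.read_fasta(emitted_dataset["fasta"])
    return {
        "gm": gm,
        "grouping": grouping,
        "genes": genes,
        "reference": reference,
        "cfg": emitted_dataset["cfg"],
    }
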