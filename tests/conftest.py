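import numpy as np
import pytest

import shmcontext as sc
from shmcontext.kmers import encode_batch
from shmcontext.model import ModelConfig, train_model


@pytest.fixture(scope="session")
def small_alleles():
    return sc.generate_alleles(5, ebox_fw1_prob=0.8, seed=1)


@pytest.fixture(scope="session")
def noiseless_params():
    """Strong planted E-box suppression, PyPy enhancement, no noise."""
    return sc.RateParams(ebox_multiplier=0.2, pypy_slope=0.15, noise_sd=0.0)


@pytest.fixture(scope="session")
def trained_setup(noiseless_params):
    """Alleles + noiseless k-mer dataset + model trained at default config.

    Targets are the ground-truth site rates, so the dataset is an exact
    function of local sequence context; shared across model, attribution
    and acceptance tests.
    """
    alleles = sc.generate_alleles(8, ebox_fw1_prob=0.8, seed=11)
    kmers, targets, agct_records = [], [], []
    for allele in alleles:
        rates = sc.assign_true_site_rates(allele, noiseless_params)
        records = sc.extract_kmers(allele)
        for rec in records:
            kmers.append(rec.kmer)
            targets.append(rates.rates[rec.central_pos - 1])
        agct_records.extend(sc.select_agct_centered(records))
    X = encode_batch(kmers)
    y = np.array(targets)
    model = train_model((X, y), ModelConfig(seed=0))
    return {
        "alleles": alleles,
        "X": X,
        "y": y,
        "model": model,
        "agct_records": agct_records,
    }
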