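"""Shared fixtures: a separable planted-motif dataset and a classifier
trained on it once per session (several test modules reuse it)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from promsnp import datasets, synthetic
from promsnp.cnn import PromoterCNN, evaluate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SEPARABLE_MOTIF = "TATAAA"
SEPARABLE_OFFSET = -30


@pytest.fixture(scope="session")
def separable_genome():
    """Genome whose every promoter carries TATAAA at -30 (inclusion 1.0).

    Uniform background keeps chance TATAAA occurrences in non-promoter
    windows rare, so motif presence/position is a sufficient statistic and
    the 2000-sequence labeled set is separable by construction.
    """
    spec = synthetic.SyntheticGenomeSpec(
        n_chromosomes=2,
        chrom_length=1_300_000,
        n_genes=1000,
        promoter_motifs=((SEPARABLE_MOTIF, SEPARABLE_OFFSET, 1.0),),
        background_composition=(0.25, 0.25, 0.25, 0.25),
        seed=2,
    )
    return synthetic.generate_annotated_genome(spec)


@pytest.fixture(scope="session")
def separable_dataset(separable_genome):
    g = separable_genome
    labeled = datasets.extract_promoter_windows(g.chromosomes, g.genes)
    labeled += datasets.extract_downstream_nonpromoters(g.chromosomes, g.genes)
    train, test = datasets.split_train_test(labeled, 0.9, seed=0)
    return train, test


@pytest.fixture(scope="session")
def trained_cnn(separable_dataset):
    """Desk-scale model trained on the separable set, plus held-out metrics."""
    train, test = separable_dataset
    Xtr, ytr = datasets.encode_set(train)
    Xte, yte = datasets.encode_set(test)
    model = PromoterCNN(conv_filters=(8, 16, 32, 64), epochs=10, seed=0)
    model.fit(Xtr, ytr)
    _, metrics = evaluate(model, Xte, yte)
    return model, metrics
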