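"""Shared fixtures.

The expensive fixtures (a trained transformer and the attribution study) are
session-scoped so learnability, benchmarking and attribution tests reuse one
training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcfkit import datakit, synthdata
from pcfkit.abt_model import ModelConfig, TrainedModel, train
from pcfkit.datakit import ChemicalRecord, Dataset, SplitSpec


@pytest.fixture(scope="session")
def synth_splits():
    """The reference synthetic study: 600 generated records, noise sd 0.3,
    curated, merged, 80/10/10 random split."""
    cfg = synthdata.SynthConfig(n_molecules=600, noise_sd=0.3, seed=0)
    raw, truth = synthdata.make_dataset(cfg)
    merged = datakit.merge_duplicates(datakit.curate(raw.records).dataset)
    tr, va, te = datakit.split(merged, SplitSpec(seed=0))
    return {"raw": raw, "truth": truth, "merged": merged,
            "train": tr, "val": va, "test": te, "config": cfg}


@pytest.fixture(scope="session")
def trained_model(synth_splits) -> TrainedModel:
    cfg = ModelConfig(hidden_dim=200, mp_iterations=3, epochs=40, patience=12, seed=0)
    return train(synth_splits["train"], synth_splits["val"], cfg)


@pytest.fixture(scope="session")
def attribution_study():
    """Graph-only model trained where the ester fragment carries nearly all
    target mass, plus an unseen evaluation pool of ester-containing
    molecules."""
    gen = synthdata.SynthConfig(n_molecules=400, noise_sd=0.2, seed=7,
                                heavy_tail_fraction=0.5)
    table = synthdata.intensive_fragment_table()
    ds, _ = synthdata.assign_targets(synthdata.generate_molecules(gen), table, gen)
    merged = datakit.merge_duplicates(datakit.curate(ds.records).dataset)
    tr, va, te = datakit.split(merged, SplitSpec(seed=1))
    cfg = ModelConfig(hidden_dim=100, mp_iterations=2, epochs=40, patience=12,
                      seed=0, use_descriptors=False, interatomic_scaler=0.1)
    model = train(tr, va, cfg)

    eval_gen = synthdata.SynthConfig(n_molecules=900, noise_sd=0.2, seed=8,
                                     heavy_tail_fraction=0.5)
    seen = set(tr.smiles) | set(va.smiles)
    pool = []
    for s in synthdata.generate_molecules(eval_gen):
        canon = datakit.curate([ChemicalRecord(s, 1.0)]).dataset.smiles[0]
        if canon not in seen and canon not in pool:
            pool.append(canon)
    return {"model": model, "table": table, "eval_pool": pool,
            "generator_config": gen, "train": tr, "val": va, "test": te}


@pytest.fixture(scope="session")
def tiny_model() -> TrainedModel:
    """A quickly trained small model for contract-style tests."""
    cfg_d = synthdata.SynthConfig(n_molecules=80, noise_sd=0.3, seed=3)
    ds, _ = synthdata.make_dataset(cfg_d)
    merged = datakit.merge_duplicates(datakit.curate(ds.records).dataset)
    tr, va, _ = datakit.split(merged, SplitSpec(seed=0, fractions=(0.8, 0.1, 0.1)))
    cfg = ModelConfig(hidden_dim=48, mp_iterations=2, epochs=3, patience=3,
                      seed=0, ffn_mult=2)
    return train(tr, va, cfg)


@pytest.fixture()
def curation_fixture() -> list[ChemicalRecord]:
    """Ten toy records exercising every curation rule; four survive."""
    return [
        ChemicalRecord("CCO", 1.0, name="ethanol"),
        ChemicalRecord("c1ccccc1", 2.0, name="benzene"),
        ChemicalRecord("CC(=O)[O-].[Na+]", 1.0, name="sodium acetate"),
        ChemicalRecord("[Fe](C)(C)", 1.0, name="iron complex"),
        ChemicalRecord("CC.OC", 1.0, name="mixture"),
        ChemicalRecord("O", 0.5, name="water"),
        ChemicalRecord("Cc1ccccc1", 1.0, purity=0.5, name="dilute toluene"),
        ChemicalRecord("CC(=O)OCC", 1.5, name="ethyl acetate"),
        ChemicalRecord("X#Y!", 1.0, name="garbage"),
        ChemicalRecord("Nc1ccccc1", 2.5, name="aniline"),
    ]


def random_smiles_pool(n: int, seed: int = 0) -> list[str]:
    """Deterministic pool of valid generated molecules for fuzz tests."""
    return synthdata.generate_molecules(
        synthdata.SynthConfig(n_molecules=n, noise_sd=0.0, seed=seed))
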