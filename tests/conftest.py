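import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plasmavar.calling import CandidateSite, SiteReadData
from plasmavar.model import train_error_model
from plasmavar.nn import TrainConfig
from plasmavar.simulate import (
    ErrorProfile,
    SimulationConfig,
    random_reference,
    simulate_alignments,
    simulate_training_table,
)


def make_site(is_alt, e_rm, e_mr, pos=100):
    return SiteReadData(site=CandidateSite("chr1", pos, "A", "C"),
                        is_alt=np.asarray(is_alt, dtype=bool),
                        e_rm=np.asarray(e_rm, dtype=float),
                        e_mr=np.asarray(e_mr, dtype=float))


def random_small_sites(rng, k_max=3, n_max=6):
    """Random tiny instances for oracle comparisons."""
    k = rng.integers(1, k_max + 1)
    sites = []
    for i in range(k):
        n = int(rng.integers(1, n_max + 1))
        sites.append(make_site(
            rng.random(n) < 0.4,
            rng.uniform(1e-4, 0.2, n),
            rng.uniform(1e-4, 0.2, n),
            pos=100 + i,
        ))
    return sites


@pytest.fixture(scope="session")
def sim_reference():
    rng = np.random.default_rng(11)
    return random_reference(3000, 0.5, rng)


@pytest.fixture(scope="session")
def sim_fixture(sim_reference, tmp_path_factory):
    """A simulated SAM + truth table with feature-dependent errors."""
    chrom, seq = next(iter(sim_reference.items()))
    cfg = SimulationConfig(
        seed=11, n_fragments=400, tumor_fraction=0.3, presence_prob=1.0,
        error_profile=ErrorProfile(base_rate=2e-3, end_coef=1.0,
                                   reverse_log_offset=0.3),
        catalog=[CandidateSite(chrom, 1500, seq[1499],
                               "A" if seq[1499] != "A" else "C")],
    )
    d = tmp_path_factory.mktemp("sim")
    sam = d / "reads.sam"
    _, reads_df, truth_df = simulate_alignments(
        cfg, reference=sim_reference, out_sam=sam,
        out_fasta=d / "ref.fa", rng=np.random.default_rng(11))
    return {"config": cfg, "sam": sam, "fasta": d / "ref.fa",
            "reads": reads_df, "truth": truth_df, "dir": d}


def read_position_rate(df):
    """Known error-rate law for selection tests: log-linear in read
    position from 1e-3 to 2e-2, independent of everything else."""
    lo, hi = np.log(1e-3), np.log(2e-2)
    t = (df["read_position"].to_numpy() - 1) / 99.0
    return np.exp(lo + (hi - lo) * t)


@pytest.fixture(scope="session")
def loco_result():
    """LOCO ranking + stepwise selection on read-position-driven errors
    with a pure-noise covariate (shared: the trainings are the slow part)."""
    from plasmavar.features import FeatureSchema
    from plasmavar.model import loco_importance, stepwise_selection

    table = simulate_training_table(
        n_positions=400_000, rate_fn=read_position_rate, beta=0.05, seed=17,
        central_base="A",
        extra_numeric={"noise": lambda rng, n: rng.normal(size=n)})
    schema = FeatureSchema.from_table(
        table.df, numeric=["read_position", "noise"], categorical=[],
        embed_trinucleotide=False)
    cfg = TrainConfig(hidden_layout=(32, 16), max_epochs=60, patience=6,
                      learning_rate=3e-3)
    ranking = loco_importance(table, schema, n_folds=5, config=cfg, seed=17)
    selected = stepwise_selection(table, ranking, schema, n_folds=5,
                                  config=cfg, seed=17)
    return {"table": table, "schema": schema, "ranking": ranking,
            "selected": selected}


@pytest.fixture(scope="session")
def e2e_model(tmp_path_factory):
    """Error model trained end to end from simulated null alignments."""
    from plasmavar.model import train_error_model
    from plasmavar.training import build_training_table

    rng = np.random.default_rng(51)
    ref = random_reference(300, 0.5, rng)
    cfg = SimulationConfig(seed=51, n_fragments=8000, reference_length=300,
                           error_profile=ErrorProfile(base_rate=1e-3))
    d = tmp_path_factory.mktemp("e2e")
    sam = d / "train.sam"
    simulate_alignments(cfg, reference=ref, out_sam=sam,
                        rng=np.random.default_rng(51))
    table = build_training_table([str(sam)], ref, beta=0.02, seed=51)
    artifact = train_error_model(
        table, config=TrainConfig(max_epochs=100, patience=8), seed=51)
    return {"reference": ref, "artifact": artifact, "config": cfg}


@pytest.fixture(scope="session")
def const_rate_artifact():
    """Error model trained on a constant-rate downsampled table.

    Shared across tests: training is the slow step and every consumer only
    needs a reasonably calibrated constant-rate model.
    """
    table = simulate_training_table(n_positions=2_000_000, rate_fn=1e-3,
                                    beta=0.01, seed=21)
    cfg = TrainConfig(max_epochs=100, patience=8)
    return train_error_model(table, config=cfg, seed=21)


def spanning_rate(df):
    """Error-rate law spanning 1e-4..1e-2, log-linear in read position."""
    lo, hi = np.log(1e-4), np.log(1e-2)
    t = (df["read_position"].to_numpy() - 1) / 99.0
    return np.exp(lo + (hi - lo) * t)


@pytest.fixture(scope="session")
def calibration_slope():
    """Binned predicted-vs-empirical mismatch-rate slope (log-log) for a
    model trained on downsampled data with rates spanning 1e-4..1e-2."""
    from plasmavar.model import ALLELE_INDEX, rescale_probabilities

    train = simulate_training_table(n_positions=4_000_000,
                                    rate_fn=spanning_rate, beta=0.005,
                                    seed=31)
    art = train_error_model(
        train, config=TrainConfig(max_epochs=100, patience=8), seed=31)
    # large held-out set: the lowest-rate bins need enough empirical
    # mismatches for the log-scale comparison to be about the model, not
    # Monte-Carlo noise; bins are weighted by their mismatch counts
    test = simulate_training_table(n_positions=2_000_000,
                                   rate_fn=spanning_rate, beta=1.0, seed=131)
    pr = rescale_probabilities(art.predict_raw(test.df),
                               test.df["ref_allele"].to_numpy(), art.beta)
    ridx = test.df["ref_allele"].map(ALLELE_INDEX).to_numpy()
    pred = 1 - pr[np.arange(len(pr)), ridx]
    true = spanning_rate(test.df)
    emp = (test.df["obs_allele"] != test.df["ref_allele"]).to_numpy()
    bins = np.quantile(true, np.linspace(0, 1, 9))
    which = np.clip(np.searchsorted(bins, true) - 1, 0, 7)
    x = np.array([pred[which == b].mean() for b in range(8)])
    y = np.array([emp[which == b].mean() for b in range(8)])
    w = np.sqrt([emp[which == b].sum() for b in range(8)])
    return float(np.polyfit(np.log10(x), np.log10(y), 1, w=w)[0])
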