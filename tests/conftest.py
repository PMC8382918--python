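"""Shared fixtures.

The planted-recovery and vertical-control studies are expensive (dozens of
full pipeline runs), so they are computed once per session and shared
between the module tests and the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from htt import domains, pipeline, simulate

N_RECOVERY_SEEDS = 20
N_VERTICAL_SIMS = 50


@pytest.fixture(scope="session")
def profiles():
    return domains.default_profiles()


@pytest.fixture(scope="session")
def scenario1():
    """One default planted-transfer scenario (three element copies)."""
    return simulate.build_ht_scenario(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_study(profiles):
    """Planted-HT recovery under the study conditions, 20 seeds.

    100-kb genomes, 14% vertical divergence, 1.5% HT divergence, 2.3x
    coverage; targeted and nontargeted tracks plus CDS calibration per
    seed.  Returns per-copy recovery counts, false-call counts, and the
    pooled calibration identities.
    """
    stats = {
        "n_copies": 0,
        "targeted_recovered": 0,
        "nontargeted_recovered": 0,
        "false_calls": 0,
        "identities": [],
        "per_seed": [],
    }
    for seed in range(1, N_RECOVERY_SEEDS + 1):
        cfg = simulate.SimConfig(seed=seed)
        sc = simulate.build_ht_scenario(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            targeted = pipeline.run_targeted(
                sc.donor_reads, [sc.recipient_genome], domain_profiles=profiles
            )
            nontargeted = pipeline.run_nontargeted(
                sc.donor_reads, sc.recipient_genome, filters={}
            )
            calib = pipeline.run_calibration(sc.donor_reads, sc.cds)
        truth = [(iv.start, iv.end) for iv in sc.truth]

        def recovered(calls):
            return sum(
                any(c.element_interval.overlap(s, e) > 0 for c in calls)
                for s, e in truth
            )

        r_t = recovered(targeted["calls"])
        r_n = recovered(nontargeted)
        stats["n_copies"] += len(truth)
        stats["targeted_recovered"] += r_t
        stats["nontargeted_recovered"] += r_n
        stats["false_calls"] += (len(targeted["calls"]) - r_t) + (len(nontargeted) - r_n)
        stats["identities"].extend(calib["histogram"].identities.tolist())
        stats["per_seed"].append(
            {"seed": seed, "targeted": r_t, "nontargeted": r_n, "n": len(truth)}
        )
    stats["identities"] = np.array(stats["identities"])
    return stats


@pytest.fixture(scope="session")
def vertical_control_study(profiles):
    """Both scans on vertical-only simulations: every call is false."""
    false_calls = 0
    for seed in range(N_VERTICAL_SIMS):
        cfg = simulate.SimConfig(seed=seed, genome_len=30_000, n_cds=10)
        sc = simulate.build_vertical_scenario(cfg, shared_te=(seed % 2 == 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            targeted = pipeline.run_targeted(
                sc.donor_reads, [sc.recipient_genome], domain_profiles=profiles
            )
            nontargeted = pipeline.run_nontargeted(
                sc.donor_reads, sc.recipient_genome, filters={}
            )
        false_calls += len(targeted["calls"]) + len(nontargeted)
    return {"n_sims": N_VERTICAL_SIMS, "false_calls": false_calls}
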