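"""Shared synthetic fixtures: one planted chromatin locus reused suite-wide.

Everything is generated at test time from fixed seeds; the study conditions
are 20 planted dyads on a 6-kb chromosome with 5e4 fragments at occupancy
0.7, the generator's default fragment-size and rotational-lattice laws.
"""

import numpy as np
import pytest

from atacnuc import bias, caller, fragments, occupancy, simulate, vplot

GENOME_LEN = 6000
N_FRAGS = 50_000
ALPHA = 0.7
REGION = ("chrS", 200, 4400)


@pytest.fixture(scope="session")
def genome():
    return simulate.make_genome(GENOME_LEN, gc=0.4, seed=0)


@pytest.fixture(scope="session")
def truth():
    return simulate.make_architecture(GENOME_LEN, n_dyads=20, alpha_true=ALPHA)


@pytest.fixture(scope="session")
def frags(truth):
    return simulate.simulate_fragments(truth, N_FRAGS, ALPHA, seed=1)


@pytest.fixture(scope="session")
def size_dist(frags):
    return fragments.size_distribution(frags)


@pytest.fixture(scope="session")
def mixture(size_dist):
    return occupancy.fit_mixture_model(size_dist)


@pytest.fixture(scope="session")
def occ_track(frags, mixture):
    return occupancy.occupancy_track(frags, REGION, mixture)


@pytest.fixture(scope="session")
def template(frags, truth, occ_track, mixture):
    V = vplot.build_vplot(frags, truth.dyads)
    target = vplot.refined_nuc_sizedist(frags, occ_track, mixture)
    return vplot.symmetrize_smooth(vplot.normalize_to_sizedist(V, target))


@pytest.fixture(scope="session")
def planted_pwm():
    return simulate.make_planted_pwm()


@pytest.fixture(scope="session")
def called(frags, size_dist, template, planted_pwm, genome, occ_track):
    """(signal, nonredundant calls, redundant calls) with the bias model."""
    return caller.call_nucleosomes(
        frags, REGION, template, size_dist,
        bias_model=planted_pwm, genome=genome, occ=occ_track,
    )
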