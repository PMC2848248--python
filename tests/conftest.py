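import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def expression_demo():
    """Planted 3-cluster expression compendium with moderate noise."""
    from srokit import synthetic_data as syn

    experiments, truth = syn.simulate_expression(
        n_clusters=3, genes_per_cluster=4, experiments=8,
        delta=2.0, noise_sd=0.3, n_reps=3, seed=1,
    )
    return experiments, truth


@pytest.fixture(scope="session")
def protein_family_demo():
    """One record per architecture/activity archetype, with planted truth."""
    from srokit import synthetic_data as syn

    templates = [
        syn.ArchitectureTemplate(("WWE", "PARP_core", "RST"), record_id="fullA"),
        syn.ArchitectureTemplate(("PARP_core", "RST"), triad=("H", "Y", "E"),
                                 loop_len=38, record_id="parp_like"),
        syn.ArchitectureTemplate(("PARP_core", "RST"), triad=("L", "H", "N"),
                                 loop_len=5, record_id="dead_core"),
        syn.ArchitectureTemplate(("PARP_core",), record_id="truncated"),
    ]
    return syn.simulate_protein_family(templates, seed=11)


def enumerate_set_partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in enumerate_set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def partition_to_labels(blocks, n):
    labels = np.empty(n, dtype=int)
    for ci, block in enumerate(sorted(blocks, key=min)):
        labels[list(block)] = ci
    return labels
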