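import numpy as np
import pytest

from looplink.xl_io import CrossLinkSet


def make_crosslink_set(pairs: dict[tuple[int, int], int],
                       protein_id: str = "p") -> CrossLinkSet:
    """CrossLinkSet with synthetic provenance matching multiplicities."""
    return CrossLinkSet(
        protein_id=protein_id,
        pairs=dict(sorted(pairs.items())),
        provenance={p: tuple(f"r{k + 1}" for k in range(m))
                    for p, m in sorted(pairs.items())},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">p\nMKSTYA\n>q\nAAAA\n")
    return path


@pytest.fixture
def toy_xls():
    return make_crosslink_set({(2, 7): 1, (4, 9): 2})


def random_overlapping_clustering(N: int, rng: np.random.Generator):
    """A random soft clustering of 1..N (clusters may overlap)."""
    from looplink.loopclust import clustering_from_members

    n_clusters = int(rng.integers(1, max(2, N // 2) + 1))
    clusters = []
    for _ in range(n_clusters):
        size = int(rng.integers(1, N + 1))
        members = tuple(sorted(rng.choice(N, size=size, replace=False) + 1))
        clusters.append(members)
    return clustering_from_members(N, clusters)


def random_hard_partition(N: int, rng: np.random.Generator):
    """A random disjoint partition of 1..N."""
    from looplink.loopclust import clustering_from_members

    labels = rng.integers(0, max(1, int(rng.integers(1, N + 1))), size=N)
    clusters: dict[int, list[int]] = {}
    for r, lab in enumerate(labels, 1):
        clusters.setdefault(int(lab), []).append(r)
    return clustering_from_members(N, [tuple(v) for v in clusters.values()])
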