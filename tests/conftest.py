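import pytest

from corescan import BipartiteMotifModel, IUPACConsensus, PromoterAlignment


@pytest.fixture
def toy_model() -> BipartiteMotifModel:
    """8-column consensus with three invariant positions (T, A, A)."""
    return BipartiteMotifModel(
        minus35=IUPACConsensus("GTAACSVR"),
        invariant_positions=frozenset({1, 2, 3}),
    )


@pytest.fixture
def promoter_alignment() -> PromoterAlignment:
    return PromoterAlignment(
        labels=("p1", "p2", "p3", "p4"),
        rows=("GTAACCCA", "GTAACGCG", "GTAACCGA", "TTAACGGG"),
    )
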