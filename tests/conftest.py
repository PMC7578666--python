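import pytest

from chemsens import (
    Direction,
    GeneratorConfig,
    InteractionRecord,
    PlantedSet,
    Taxon,
    generate_benchmark,
)


def make_record(
    gene="ESR1",
    chemical="bisphenol A",
    direction=Direction.INCREASE,
    taxon=Taxon.HOMO,
    pmid=12345,
    uses=("industrial",),
    use_description="",
):
    return InteractionRecord(
        chemical=chemical,
        gene=gene,
        direction=direction,
        taxon=taxon,
        pmid=pmid,
        uses=tuple(uses),
        use_description=use_description,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def mixed_records():
    """Ten records spanning taxa, directions and use terms."""
    return [
        make_record("ESR1", "bisphenol A", Direction.INCREASE, Taxon.HOMO, 111, ("industrial",)),
        make_record("TP53", "cisplatin", Direction.DECREASE, Taxon.MUS, 222, ("pharmaceutical", "research")),
        make_record("CYP1A1", "benzo[a]pyrene", Direction.INCREASE, Taxon.RATTUS, 333, ("pollutant",)),
        make_record("ESR1", "bisphenol A", Direction.INCREASE, Taxon.MUS, 111, ("industrial",)),
        make_record("HMOX1", "cadmium", Direction.INCREASE, Taxon.HOMO, 444, ("industrial", "pollutant")),
        make_record("TP53", "doxorubicin", Direction.UNSPECIFIED, Taxon.HOMO, 555, ("pharmaceutical",)),
        make_record("GSTP1", "ozone", Direction.DECREASE, Taxon.RATTUS, 666, ("environment",)),
        make_record("NQO1", "sulforaphane", Direction.INCREASE, Taxon.MUS, 777, ("food components",)),
        make_record("CYP1A1", "tcdd", Direction.INCREASE, Taxon.HOMO, 888, ("pollutant",)),
        make_record("ABCB1", "estradiol", Direction.DECREASE, Taxon.HOMO, 999, ("endobiotic",)),
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact synthetic study shared by read-only tests."""
    config = GeneratorConfig(
        n_genes=300,
        n_chemicals=60,
        planted_sets=[
            PlantedSet("PLANTED_HIGH_A", 25, 3.0, "high"),
            PlantedSet("PLANTED_LOW_A", 25, 3.0, "low"),
        ],
        n_null_sets=8,
        null_set_size=25,
        seed=42,
    )
    records, presence, collection, labels, truth = generate_benchmark(config)
    return {
        "config": config,
        "records": records,
        "presence": presence,
        "collection": collection,
        "labels": labels,
        "truth": truth,
    }
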