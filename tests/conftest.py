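import pytest

from diaspeclib.speclib_io import FragmentIon, PrecursorRecord, SpectralLibrary


def make_fragment(intensity=100.0, number=3, series="y", charge=1, mz=500.0):
    return FragmentIon(
        product_mz=mz,
        fragment_charge=charge,
        series_type=series,
        series_number=number,
        library_intensity=intensity,
    )


def make_precursor(
    seq="PEPTIDEK",
    charge=2,
    rt=50.0,
    n_fragments=3,
    intensities=None,
    protein="P00001",
    modified=None,
):
    intensities = intensities if intensities is not None else [100.0] * n_fragments
    frags = [
        make_fragment(intensity=inten, number=i + 1, series="y" if i % 2 == 0 else "b")
        for i, inten in enumerate(intensities)
    ]
    return PrecursorRecord(
        modified_sequence=modified or seq,
        stripped_sequence=seq,
        precursor_charge=charge,
        precursor_mz=450.0 + charge,
        normalized_rt=rt,
        fragments=frags,
        protein_group=[protein],
        leading_protein=protein,
    )


def make_library(precursors):
    return SpectralLibrary(list(precursors), provenance={"source": "test"})


@pytest.fixture
def tiny_library():
    """Five precursors over two peptides and two proteins."""
    return make_library(
        [
            make_precursor("AAAAAAAK", charge=2, rt=10.0, protein="P00001"),
            make_precursor("AAAAAAAK", charge=3, rt=10.0, protein="P00001"),
            make_precursor("CCCCCCCR", charge=2, rt=40.0, protein="P00002"),
            make_precursor("CCCCCCCR", charge=3, rt=40.0, protein="P00002"),
            make_precursor("CCCCCCCR", charge=4, rt=40.0, protein="P00002"),
        ]
    )
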