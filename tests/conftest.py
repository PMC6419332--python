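import pytest

from refconcord import synthetic_data as sd


def make_pair(length=20_000, seed=7, n_deletions=2, n_insertions=2,
              n_inversions=1, edit_len=(100, 600), gc=0.42):
    edits = sd.EditSpec(n_deletions=n_deletions, deletion_length_range=edit_len,
                        n_insertions=n_insertions, insertion_length_range=edit_len,
                        n_inversions=n_inversions, inversion_length_range=edit_len,
                        seed=seed)
    return sd.generate_assembly_pair(length, gc, edits)


@pytest.fixture(scope="session")
def small_pair():
    """20 kb assembly pair with deletions, insertions and an inversion."""
    return make_pair()


@pytest.fixture(scope="session")
def small_bundle(small_pair):
    """1000-variant call sets with 50 unconvertible, 30 PD, 10 GD injected."""
    spec = sd.DiscordanceSpec(n_position_discordant=30, n_genotype_discordant=10,
                              lc_enrichment=8.0, depth_shift=0.2, seed=11)
    return sd.simulate_callsets(small_pair, 1000, spec, n_unconvertible=50,
                                n_target_only=10)


@pytest.fixture(scope="session")
def identity_pair():
    """Edit-free pair: target equals source, one identity chain."""
    return sd.generate_assembly_pair(5000, 0.42, sd.EditSpec(seed=3))


@pytest.fixture()
def fixture_dir(tmp_path, small_bundle):
    sd.write_fixture(small_bundle, tmp_path / "fx")
    return tmp_path / "fx"
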