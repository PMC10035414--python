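import pytest

from famscan import family_identification as fi
from famscan.synthetic_data import (
    NOISE_FREE,
    make_fixture,
    preset_cp159,
    preset_tiny,
)


@pytest.fixture(scope="session")
def cp159_bundle():
    return make_fixture(preset_cp159(), seed=1)


@pytest.fixture(scope="session")
def cp159_dir(cp159_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cp159")
    paths = cp159_bundle.write(outdir)
    return paths


@pytest.fixture(scope="session")
def cp159_profile(cp159_bundle):
    return fi.build_profile(cp159_bundle.seed_alignment)


@pytest.fixture(scope="session")
def cp159_hits(cp159_bundle, cp159_profile):
    return {
        p.id: fi.scan_sequence(cp159_profile, p) for p in cp159_bundle.proteins
    }


@pytest.fixture(scope="session")
def noisefree_bundle():
    preset = preset_tiny(
        n_valid=9,
        n_chromosomes=2,
        n_duplicate_decoys=2,
        n_truncated_decoys=2,
        unexpressed_member_ranks=(2,),
        go_salt_member_ranks=(1, 5),
        deg_profiles={
            3: ("A1", (0.0, -1.8, -2.0, -2.4)),
            5: ("A2", (0.0, 0.5, 0.5, 2.2)),
        },
        noise=NOISE_FREE,
        expression_noise_sd=0.0,
        qpcr_noise_sd=0.0,
        name="noisefree",
    )
    return make_fixture(preset, seed=11)


@pytest.fixture(scope="session")
def noisefree_profile(noisefree_bundle):
    return fi.build_profile(noisefree_bundle.seed_alignment)
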