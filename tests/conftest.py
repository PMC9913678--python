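import pytest

import groomnet as gn


@pytest.fixture(scope="session")
def design():
    roster, phases, season_rule = gn.default_design()
    return {
        "roster": roster,
        "phases": phases,
        "season_rule": season_rule,
        "catalog": gn.default_catalog(),
    }


@pytest.fixture(scope="session")
def small_cfg():
    # a few sessions per stratum keep the suite fast while covering all cells
    return gn.default_sim_config(seed=11, sessions_per_stratum=4)


@pytest.fixture(scope="session")
def scan_table(small_cfg):
    table, truth = gn.generate_scans(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def stratified(small_cfg, scan_table):
    table, _ = scan_table
    return gn.assign_strata(table, small_cfg.phases, small_cfg.season_rule)


@pytest.fixture(scope="session")
def nets(small_cfg, stratified):
    return gn.build_networks(
        stratified, small_cfg.catalog, small_cfg.phases, small_cfg.roster
    )


@pytest.fixture(scope="session")
def index_table(small_cfg, stratified, nets):
    return gn.build_index_table(
        stratified, nets, small_cfg.phases, small_cfg.roster, small_cfg.catalog
    )
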