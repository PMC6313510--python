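"""Virtual-site construction: layout, hazard law, cranes, replenishment."""

import numpy as np
import pytest
import scipy.stats

from crewsim.config import ConfigurationError, SiteConfig
from crewsim.site import SiteGrid, consume_and_replenish, generate_site, update_crane_zones


@pytest.fixture(scope="module")
def site():
    return generate_site(SiteConfig(), np.random.default_rng(7))


def test_building_layout_counts(site):
    assert int(site.is_building.sum()) == 3600
    assert not (site.is_building & site.is_road).any()
    # workload only on building cells, within 1..20
    assert (site.workload[site.is_building] >= 1).all()
    assert (site.workload[site.is_building] <= 20).all()
    assert (site.workload[~site.is_building] == 0).all()


def test_hazard_bounds(site):
    assert (site.base_hazard >= 0).all() and (site.base_hazard <= 200).all()
    assert (site.effective_hazard >= 0).all() and (site.effective_hazard <= 200).all()
    assert (site.effective_hazard >= site.base_hazard).all()


@pytest.mark.parametrize("mode", [50.0, 100.0, 150.0])
def test_base_hazard_is_triangular(mode):
    grid = generate_site(SiteConfig(hazard_mode=mode), np.random.default_rng(11))
    sample = grid.base_hazard[grid.building_idx]
    stat = scipy.stats.kstest(sample, scipy.stats.triang(c=mode / 200, scale=200).cdf)
    assert stat.pvalue > 0.01
    assert abs(sample.mean() - (0 + mode + 200) / 3) < 3.0


def test_same_seed_gives_identical_sites():
    a = generate_site(SiteConfig(), np.random.default_rng(42))
    b = generate_site(SiteConfig(), np.random.default_rng(42))
    for attr in ("workload", "base_hazard", "crane_hazard", "has_constraint"):
        np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))
    ra, rb = np.random.default_rng(1), np.random.default_rng(1)
    for _ in range(30):
        update_crane_zones(a, ra)
        update_crane_zones(b, rb)
    np.testing.assert_array_equal(a.crane_hazard, b.crane_hazard)


def test_crane_danger_zone_hazard_range(site):
    covered = np.flatnonzero(site.crane_hazard > 0)
    assert covered.size > 0
    assert (site.crane_hazard[covered] >= 160).all()
    assert (site.crane_hazard[covered] <= 200).all()
    assert (site.effective_hazard[covered] >= 160).all()


def test_full_sweep_covers_exactly_the_jib_disk(site):
    """The union of all heading sectors is the disk of the jib radius,
    verified against a brute-force geometric enumeration."""
    crane = site.cranes[0]
    swept = np.unique(np.concatenate(crane.sectors))
    px, py = crane.pivot
    expected = []
    for idx in range(site.width * site.height):
        x, y = idx % site.width, idx // site.width
        if (x + 0.5 - px) ** 2 + (y + 0.5 - py) ** 2 <= crane.jib_length**2:
            expected.append(idx)
    np.testing.assert_array_equal(swept, np.asarray(expected))
    # sectors are disjoint: each cell belongs to exactly one heading
    assert sum(s.size for s in crane.sectors) == swept.size


def test_rotation_clears_previous_sector():
    grid = generate_site(SiteConfig(), np.random.default_rng(3))
    rng = np.random.default_rng(4)
    crane = grid.cranes[0]
    old_cells = crane.sectors[crane.heading_idx]
    update_crane_zones(grid, rng)
    new_cells = crane.sectors[crane.heading_idx]
    others = [c.sectors[c.heading_idx] for c in grid.cranes[1:]]
    still_hot = np.concatenate([new_cells] + others)
    gone = np.setdiff1d(old_cells, still_hot)
    assert (grid.crane_hazard[gone] == 0).all()
    assert (grid.crane_hazard[new_cells] >= 160).all()


def test_consume_and_replenish_cycle():
    grid = generate_site(SiteConfig(), np.random.default_rng(9))
    rng = np.random.default_rng(10)
    cell = int(grid.building_idx[0])
    draws = []
    for _ in range(3000):
        consume_and_replenish(grid, cell, float(grid.workload[cell]), rng)
        draws.append(grid.workload[cell])
    draws = np.asarray(draws)
    assert draws.min() >= 1 and draws.max() <= 20
    # long-run mean of U{1..20}
    assert abs(draws.mean() - 10.5) < 0.4


def test_depletion_is_permanent_without_replenishment():
    grid = generate_site(SiteConfig(replenish=False), np.random.default_rng(9))
    rng = np.random.default_rng(10)
    cell = int(grid.building_idx[5])
    consume_and_replenish(grid, cell, float(grid.workload[cell]), rng)
    assert grid.workload[cell] == 0
    with pytest.raises(ValueError):
        grid.consume(cell, 1.0, rng)


def test_invalid_configuration_rejected():
    with pytest.raises(ConfigurationError):
        SiteConfig(hazard_mode=250.0)
    with pytest.raises(ConfigurationError):
        SiteConfig(grid_width=-1)


def test_snapshot_export(tmp_path, site):
    paths = site.write_layers(str(tmp_path / "site"))
    assert len(paths) == 3
    for p in paths:
        with open(p) as fh:
            header = fh.readline()
            assert "width=92" in header and "height=84" in header
        layer = np.loadtxt(p)
        assert layer.shape == (84, 92)
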