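# Landsat acquisition manifest for the Duhok winter-crop assessment
# (path 170 / row 034).  Dates are year and Julian day (YYYY-DDD); spring
# scenes are pre-harvest (March-June), summer scenes post-harvest
# (July-September).  One spring scene per period carries
# `segmentation: true` (the scene fed to object segmentation).
# Band rasters are not bundled; this manifest documents the scene list.
crs: "EPSG:32638"
periods:
  - id: A
    label: pre-Anfal
    years: [1984, 1987]
    scenes:
      - {date: "1984-158", season: spring}
      - {date: "1985-160", season: spring}
      - {date: "1986-115", season: spring}
      - {date: "1986-163", season: spring}
      - {date: "1987-150", season: spring, segmentation: true}
      - {date: "1984-222", season: summer}
      - {date: "1986-179", season: summer}
      - {date: "1987-198", season: summer}
      - {date: "1987-246", season: summer}
  - id: B
    label: post-Anfal
    years: [1989, 1991]
    scenes:
      - {date: "1989-35", season: spring}
      - {date: "1990-86", season: spring}
      - {date: "1990-134", season: spring}
      - {date: "1990-166", season: spring}
      - {date: "1991-129", season: spring, segmentation: true}
      - {date: "1989-179", season: summer}
      - {date: "1989-195", season: summer}
      - {date: "1989-211", season: summer}
      - {date: "1990-190", season: summer}
  - id: C
    label: reconstruction
    years: [1998, 2002]
    scenes:
      - {date: "1998-100", season: spring}
      - {date: "1998-164", season: spring}
      - {date: "1999-71", season: spring}
      - {date: "2000-154", season: spring}
      - {date: "2001-116", season: spring}
      - {date: "2001-148", season: spring}
      - {date: "2001-164", season: spring}
      - {date: "2002-151", season: spring, segmentation: true}
      - {date: "1999-231", season: summer}
      - {date: "2000-234", season: summer}
      - {date: "2000-250", season: summer}
      - {date: "2002-231", season: summer}
  - id: D
    label: present
    years: [2011, 2014]
    scenes:
      - {date: "2011-168", season: spring}
      - {date: "2013-109", season: spring}
      - {date: "2013-125", season: spring}
      - {date: "2013-157", season: spring}
      - {date: "2014-64", season: spring}
      - {date: "2014-80", season: spring}
      - {date: "2014-96", season: spring}
      - {date: "2014-112", season: spring}
      - {date: "2014-144", season: spring}
      - {date: "2014-160", season: spring, segmentation: true}
      - {date: "2011-184", season: summer}
      - {date: "2011-232", season: summer}
      - {date: "2012-179", season: summer}
      - {date: "2013-173", season: summer}
      - {date: "2013-189", season: summer}
      - {date: "2013-237", season: summer}
      - {date: "2014-176", season: summer}
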