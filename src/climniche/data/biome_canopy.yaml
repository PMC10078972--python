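# Biome -> canopy class used to collapse per-species biome proportions into
# the 3-state canopy character.  Forest-type biomes (more or less continuous
# tree canopy) are "closed"; grassland / shrubland / tundra / desert biomes
# are "open".  The alternate scheme differs only in treating Mediterranean
# forests, woodlands & scrub as open habitat.
primary:
  "Tropical & Subtropical Moist Broadleaf Forests": closed
  "Tropical & Subtropical Dry Broadleaf Forests": closed
  "Tropical & Subtropical Coniferous Forests": closed
  "Temperate Broadleaf & Mixed Forests": closed
  "Temperate Conifer Forests": closed
  "Boreal Forests/Taiga": closed
  "Tropical & Subtropical Grasslands, Savannas & Shrublands": open
  "Temperate Grasslands, Savannas & Shrublands": open
  "Flooded Grasslands & Savannas": open
  "Montane Grasslands & Shrublands": open
  "Tundra": open
  "Mediterranean Forests, Woodlands & Scrub": closed
  "Deserts & Xeric Shrublands": open
  "Mangroves": closed
mediterranean_open:
  "Mediterranean Forests, Woodlands & Scrub": open
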