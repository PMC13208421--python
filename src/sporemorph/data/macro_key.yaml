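# Macromorphological and ecological key (experimental, best-effort).
# Encoded as data only; evaluation asks the caller yes/no questions keyed by
# couplet id and branch.  Unlike the microscopy key this key relies on
# qualitative field characters and is not a supported quantitative
# classifier.
version: 1
couplets:
  1:
    a:
      question: >-
        Stipe with a well-defined reticulum; rounded pores; smell of
        fermented fruits; preferably calcareous Mediterranean habitats?
      label: poikilochromus
    b:
      question: >-
        Stipe devoid of reticulum (or nearly so); angular pores; indistinct
        mushroomy smell?
      goto: 2
  2:
    a:
      question: >-
        Pileus slightly viscous or silky with yellow to raspberry-red
        surface; acute pileus margin; lemon-yellow context turning dark blue
        with greenish shades; temperate habitats?
      label: pulverulentus
    b:
      question: >-
        Pileus persistently felty; involute or obtuse margin; whitish/pale
        yellow context turning deep ink blue; Mediterranean thermophilic
        habitats?
      goto: 3
  3:
    a:
      question: >-
        Pileus snuff brown to buff brown; pores and stipe lemon yellow,
        often dark brick red at the base?
      label: mediterraneensis f. mediterraneensis
    b:
      question: >-
        Pileus light buff to pale yellow; pores pale yellow; stipe light
        yellow without brown or red shades?
      label: mediterraneensis f. pallidus
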