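# Geological/biogeographic event windows (ages in Myr; start >= end;
# point events have start == end).  The Palaeocene+Eocene span is an
# interpretation (66-33.9 Ma, standard chronostratigraphic bounds).
- name: South America-Antarctica split
  start_age: 50
  end_age: 50
- name: Boreotropical conditions (Palaeocene-Eocene)
  start_age: 66
  end_age: 33.9
- name: Rapid north Andean uplift
  start_age: 8
  end_age: 5
- name: Panama isthmus biotic interchange
  start_age: 20
  end_age: 0
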