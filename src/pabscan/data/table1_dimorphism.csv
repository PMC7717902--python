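species,group,male_mass_g,female_mass_g,male_canine_mm,female_canine_mm,testes_mass_g,male_mass_for_testes_g
Callithrix jacchus,haplorrhine,317,324,5.08,4.81,1.3,320
Daubentonia madagascariensis,strepsirrhine,2621,2446,,,,
Eulemur rubriventer,strepsirrhine,1980,1940,10.49,9.98,1.76,2512
Galago senegalensis,strepsirrhine,227,199,4.01,3.61,1.66,210
Gorilla gorilla,haplorrhine,170400,71500,30.26,17.4,29.6,169000
Homo sapiens,haplorrhine,72100,62100,10.85,9.97,40.5,66825
Macaca mulatta,haplorrhine,11000,8800,16.97,8.13,46,9200
Microcebus murinus,strepsirrhine,59,63,2.07,2.08,2.49,60
Nycticebus coucang,strepsirrhine,679,626,7.05,6.8,1.2,1058
Otolemur garnettii,strepsirrhine,794,734,6.53,6.04,8.93,320
Pan troglodytes,haplorrhine,59700,45800,21.72,15.26,128.9,44670
Pongo pygmaeus,haplorrhine,78500,35800,27,15.95,35.3,74640
Prolemur simus,strepsirrhine,2532,2248,5.94,5.91,,
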