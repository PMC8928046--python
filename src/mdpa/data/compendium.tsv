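activity	met_value	category
walking, casual pace	2.8	light
walking, brisk pace	4.3	moderate
walking, very brisk	5.0	moderate
hiking, cross country	6.0	vigorous
jogging	7.0	vigorous
running, 8 km/h	8.3	vigorous
cycling, leisure	4.0	moderate
cycling, moderate effort	6.8	vigorous
swimming, leisurely	6.0	vigorous
gardening, general	3.8	moderate
mowing lawn, push mower	5.0	moderate
housework, general cleaning	3.3	moderate
vacuuming	3.3	moderate
dancing, general	5.0	moderate
yoga	2.5	light
golf, walking with clubs	4.3	moderate
tennis, doubles	4.5	moderate
badminton, social	5.5	moderate
stair climbing, slow	4.0	moderate
resistance training, general	3.5	moderate
tai chi	3.0	moderate
table tennis	4.0	moderate
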