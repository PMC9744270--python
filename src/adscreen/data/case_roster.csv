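case_id,sex,current_age,race,age_at_diagnosis,age_is_upper_bound,bmi_min,bmi_max,hba1c_min,hba1c_max,regimen,long_term_insulin,family_history,multigenerational_family_history,ketosis_history_adult,c_peptide_status,pattern_label
AD01,M,41,Black,35,false,23.9,27.8,5.3,11.2,metformin,false,true,true,true,normal_or_high,KPD
AD02,F,67,White,42,false,21.0,25.2,6.2,9.1,metformin;basal insulin;liraglutide,true,false,false,false,untested,ISNM
AD03,M,61,White,35,false,16.8,23.8,7.5,8.6,metformin;glipizide,false,true,true,false,untested,ISNM
AD04,F,62,White,52,false,23.0,24.0,6.2,6.7,metformin;glimepiride,false,false,false,false,untested,ISNM
AD05,M,69,White,58,false,23.4,27.3,7.0,7.3,metformin,false,false,false,false,untested,ISNM
AD06,M,74,White,68,false,22.1,24.0,6.1,6.4,,false,true,true,false,untested,MARD
AD07,F,72,Asian,60,false,18.5,22.5,5.8,8.8,metformin;empagliflozin,false,false,false,false,untested,ISNM
AD08,M,84,Asian,67,false,19.2,22.2,6.2,7.3,glipizide,false,false,false,false,untested,MARD
AD09,M,67,White,62,true,25.6,25.6,6.2,6.7,pioglitazone;metformin;prednisone,false,false,false,false,untested,MARD
AD10,M,76,White,70,true,24.1,26.2,5.5,6.2,sitagliptin,false,false,false,false,untested,MARD
AD11,F,70,White,65,false,22.3,25.7,5.5,6.1,metformin,false,false,false,false,untested,MARD
AD12,M,89,White,77,false,17.5,21.8,5.8,6.3,metformin,false,false,false,false,untested,MARD
AD13,F,77,White,58,false,21.8,25.6,5.6,9.4,,false,false,false,false,untested,ISNM
AD14,M,68,White,49,false,22.4,25.9,6.6,8.1,metformin,false,true,false,false,untested,ISNM
AD15,F,83,Unknown,67,false,18.9,21.5,5.3,6.1,,false,true,false,false,untested,MARD
AD16,M,54,Unknown,44,false,23.3,26.2,,,metformin,false,false,false,false,untested,ISNM
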